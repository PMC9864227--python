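"""MAG quality scoring and tiering from completeness/contamination estimates.

The quality score is ``completeness - 5 * contamination`` (both in percent).
Tiers:

* **high** — score > 50, completeness > 80, contamination < 5
* **medium** — score > 50, 50 <= completeness <= 80, contamination < 10
* **fail** — everything else (discarded by :func:`filter_mags`)

Completeness exactly 80 is medium (the medium band is closed, the high band
open); a score of exactly 50 fails. Contamination is uncapped for scoring, so
the score can go negative; the tier rules enforce the caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TIER_HIGH = "high"
TIER_MEDIUM = "medium"
TIER_FAIL = "fail"


def quality_score(completeness: float, contamination: float) -> float:
    """completeness% - 5 x contamination%."""
    if not 0.0 <= completeness <= 100.0:
        raise ValueError(f"completeness {completeness!r} outside [0, 100]")
    if contamination < 0.0:
        raise ValueError(f"contamination {contamination!r} must be >= 0")
    return completeness - 5.0 * contamination


def classify_tier(completeness: float, contamination: float) -> str:
    score = quality_score(completeness, contamination)
    if score > 50.0 and completeness > 80.0 and contamination < 5.0:
        return TIER_HIGH
    if score > 50.0 and 50.0 <= completeness <= 80.0 and contamination < 10.0:
        return TIER_MEDIUM
    return TIER_FAIL


@dataclass(frozen=True)
class MagRecord:
    """One genome bin with its quality estimates and derived score/tier."""

    mag_id: str
    library: str
    completeness: float
    contamination: float
    n50: float | None = None
    strain_heterogeneity: float | None = None
    quality_score: float = field(init=False)
    tier: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "quality_score", quality_score(self.completeness, self.contamination)
        )
        object.__setattr__(
            self, "tier", classify_tier(self.completeness, self.contamination)
        )


def score_mags(df: pd.DataFrame) -> pd.DataFrame:
    """Add quality_score and tier columns to a (mag_id, completeness, contamination) table."""
    required = {"mag_id", "completeness", "contamination"}
    if not required.issubset(df.columns):
        raise ValueError(f"MAG table needs columns {sorted(required)}")
    out = df.copy()
    out["quality_score"] = [
        quality_score(c, x) for c, x in zip(df["completeness"], df["contamination"])
    ]
    out["tier"] = [
        classify_tier(c, x) for c, x in zip(df["completeness"], df["contamination"])
    ]
    return out


def filter_mags(records: list[MagRecord]) -> tuple[list[MagRecord], list[tuple[str, str]]]:
    """Keep high/medium MAGs; log each rejected id with the violated condition."""
    ids = [r.mag_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate mag_id(s): {sorted(dupes)}")
    retained, log = [], []
    for r in records:
        if r.tier in (TIER_HIGH, TIER_MEDIUM):
            retained.append(r)
        else:
            log.append((r.mag_id, _fail_reason(r)))
    return retained, log


def _fail_reason(r: MagRecord) -> str:
    if r.quality_score <= 50.0:
        return f"quality score {r.quality_score:.2f} <= 50"
    if r.completeness < 50.0:
        return f"completeness {r.completeness:.2f} < 50"
    if r.completeness > 80.0 and r.contamination >= 5.0:
        return f"contamination {r.contamination:.2f} >= 5 at completeness > 80"
    return f"contamination {r.contamination:.2f} >= 10"


def read_mags_tsv(path) -> list[MagRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        MagRecord(
            mag_id=str(r.mag_id),
            library=str(getattr(r, "library", "")),
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            n50=float(r.n50) if hasattr(r, "n50") else None,
            strain_heterogeneity=(
                float(r.strain_heterogeneity)
                if hasattr(r, "strain_heterogeneity")
                else None
            ),
        )
        for r in df.itertuples()
    ]


def write_mags_tsv(path, records: list[MagRecord]) -> None:
    rows = [
        {
            "mag_id": r.mag_id,
            "library": r.library,
            "completeness": r.completeness,
            "contamination": r.contamination,
            "n50": r.n50,
            "strain_heterogeneity": r.strain_heterogeneity,
            "quality_score": r.quality_score,
            "tier": r.tier,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
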