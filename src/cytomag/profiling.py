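"""Coverage-based abundance profiling with a 10x detection-limit rule.

Fold coverage of a genome in a library is ``L * N / G`` — read length times
mapped reads over genome size. A genome is detected in a library only when
its coverage reaches 10x ("minimum of 10x" is inclusive: exactly 10 counts);
anything lower is below detection limit (BDL) and excluded from relative
abundance, which normalizes each detected genome's coverage by the library's
total above-BDL coverage. The per-library detection limit, expressed as a
relative abundance, is therefore ``100 * 10 / total_above_bdl_coverage``.

Coverage is carried at full precision; a ``rounded`` mode reproduces printed
reports that normalize over whole-fold coverages. Pseudo-mapping assigns each
read to the indexed genome sharing the most canonical k-mers (ties discarded),
standing in for a full aligner at the resolution this profiling needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import hashed_kmers, splitmix64, canonical_kmers
from ._util import mean_sd, round_half_up

BDL_THRESHOLD = 10.0


def coverage(read_length: float, n_reads: float, genome_size: float) -> float:
    """Fold coverage L * N / G."""
    if read_length <= 0:
        raise ValueError("read length must be positive")
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_reads < 0:
        raise ValueError("read count must be >= 0")
    return read_length * n_reads / genome_size


@dataclass
class CoverageRecord:
    """One (library, genome) cell: reads, coverage, BDL flag, relative abundance."""

    library: str
    gotu_id: str
    coverage: float
    n_reads: int | None = None
    read_length: float | None = None
    genome_size: float | None = None
    bdl: bool | None = None
    rel_abundance: float | None = None


@dataclass
class LibraryProfile:
    """All coverage records of one library plus its detection limit."""

    library: str
    records: list[CoverageRecord]
    total_above_bdl_coverage: float = 0.0
    detection_limit_pct: float | None = None

    def abundances(self) -> dict[str, float]:
        return {
            r.gotu_id: r.rel_abundance for r in self.records if not r.bdl
        }

    def detected(self) -> list[str]:
        return [r.gotu_id for r in self.records if not r.bdl]


def apply_detection_limit(
    records: list[CoverageRecord], threshold: float = BDL_THRESHOLD
) -> list[CoverageRecord]:
    """Flag records below ``threshold`` coverage as BDL (exactly 10 is detected)."""
    for r in records:
        r.bdl = r.coverage < threshold
        if r.bdl:
            r.rel_abundance = None
    return records


def relative_abundance(records: list[CoverageRecord]) -> list[CoverageRecord]:
    """Percent of each detected genome's coverage in the library's detected total."""
    if any(r.bdl is None for r in records):
        raise ValueError("apply_detection_limit before relative_abundance")
    total = sum(r.coverage for r in records if not r.bdl)
    for r in records:
        if not r.bdl:
            r.rel_abundance = 100.0 * r.coverage / total
    return records


def detection_limit_pct(
    total_above_bdl_coverage: float, threshold: float = BDL_THRESHOLD
) -> float | None:
    """Smallest detectable relative abundance: 100 * threshold / detected total."""
    if total_above_bdl_coverage <= 0:
        return None
    return 100.0 * threshold / total_above_bdl_coverage


def profile_library(
    library: str,
    counts: dict[str, int] | None = None,
    genome_sizes: dict[str, float] | None = None,
    read_length: float | None = None,
    coverages: dict[str, float] | None = None,
    threshold: float = BDL_THRESHOLD,
    rounded: bool = False,
) -> LibraryProfile:
    """Build a LibraryProfile from read counts (plus L and G) or direct coverages.

    ``rounded=True`` rounds each coverage half-up to whole folds before BDL
    masking and normalization, matching reports printed at integer coverage.
    """
    records: list[CoverageRecord] = []
    if coverages is not None:
        for gotu in sorted(coverages):
            records.append(
                CoverageRecord(library=library, gotu_id=gotu, coverage=float(coverages[gotu]))
            )
    else:
        if counts is None or genome_sizes is None or read_length is None:
            raise ValueError("provide either coverages or (counts, genome_sizes, read_length)")
        missing = set(counts) - set(genome_sizes)
        if missing:
            raise ValueError(f"no genome size for: {sorted(missing)}")
        for gotu in sorted(counts):
            cov = coverage(read_length, counts[gotu], genome_sizes[gotu])
            records.append(
                CoverageRecord(
                    library=library,
                    gotu_id=gotu,
                    coverage=cov,
                    n_reads=int(counts[gotu]),
                    read_length=read_length,
                    genome_size=genome_sizes[gotu],
                )
            )
    if rounded:
        for r in records:
            r.coverage = round_half_up(r.coverage, 0)
    apply_detection_limit(records, threshold)
    relative_abundance(records)
    total = sum(r.coverage for r in records if not r.bdl)
    return LibraryProfile(
        library=library,
        records=records,
        total_above_bdl_coverage=total,
        detection_limit_pct=detection_limit_pct(total, threshold),
    )


def summarize_detection_limits(
    profiles: list[LibraryProfile],
) -> tuple[float, float | None]:
    """Mean and sample (n-1) sd of the per-library detection limits."""
    limits = [p.detection_limit_pct for p in profiles if p.detection_limit_pct is not None]
    if not limits:
        raise ValueError("no library has a defined detection limit")
    return mean_sd(limits)


# ---------------------------------------------------------------------------
# k-mer pseudo-mapping


@dataclass
class MappingResult:
    """Per-genome read tallies from pseudo-mapping."""

    counts: dict[str, int]
    n_unassigned: int = 0
    n_ambiguous: int = 0
    assignments: list[str | None] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())


class KmerIndex:
    """Maps hashed canonical k-mers to the genomes containing them."""

    def __init__(self, genomes: dict[str, str], k: int = 21):
        if not genomes:
            raise ValueError("cannot index an empty genome set")
        self.k = k
        self.names = sorted(genomes)
        self._lookup: dict[int, int] = {}
        # genomes sharing a k-mer get a merged slot; slot id -> member genome indices
        self._slots: list[tuple[int, ...]] = []
        slot_of: dict[tuple[int, ...], int] = {}
        per_genome = {g: hashed_kmers(genomes[g], k) for g in self.names}
        for gi, g in enumerate(self.names):
            for h in per_genome[g].tolist():
                prev = self._lookup.get(h)
                members = (gi,) if prev is None else tuple(sorted(set(self._slots[prev] + (gi,))))
                slot = slot_of.get(members)
                if slot is None:
                    slot = len(self._slots)
                    self._slots.append(members)
                    slot_of[members] = slot
                self._lookup[h] = slot

    def assign(self, read: str, min_hits: int = 5) -> str | None:
        """Genome sharing the most k-mers with the read, or None (tie / too few)."""
        kmers = canonical_kmers(read, self.k)
        if kmers.size == 0:
            return None
        hits = np.zeros(len(self.names), dtype=np.int64)
        lookup = self._lookup
        slots = self._slots
        for h in np.unique(splitmix64(kmers)).tolist():
            slot = lookup.get(h)
            if slot is not None:
                for gi in slots[slot]:
                    hits[gi] += 1
        best = int(hits.argmax())
        if hits[best] < min_hits:
            return None
        if (hits == hits[best]).sum() > 1:
            return "__tie__"
        return self.names[best]


def pseudo_map(
    reads: list[tuple[str, str]] | list[str],
    genomes: dict[str, str] | KmerIndex,
    k: int = 21,
    min_hits: int = 5,
) -> MappingResult:
    """Assign each read to the genome sharing the most canonical k-mers.

    Reads with fewer than ``min_hits`` shared k-mers are unassigned; reads
    tying between genomes are discarded and tallied as ambiguous.
    """
    index = genomes if isinstance(genomes, KmerIndex) else KmerIndex(genomes, k)
    counts = {name: 0 for name in index.names}
    result = MappingResult(counts=counts)
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        if len(seq) < index.k:
            raise ValueError("read shorter than k")
        hit = index.assign(seq, min_hits)
        if hit is None:
            result.n_unassigned += 1
            result.assignments.append(None)
        elif hit == "__tie__":
            result.n_ambiguous += 1
            result.assignments.append(None)
        else:
            counts[hit] += 1
            result.assignments.append(hit)
    return result


# ---------------------------------------------------------------------------
# rarefaction


def rarefaction_curve(
    assignments: list[str | None],
    genome_sizes: dict[str, float],
    read_length: float,
    depths: list[int],
    reps: int = 10,
    seed: int = 0,
    threshold: float = BDL_THRESHOLD,
) -> pd.DataFrame:
    """Detected-genome count and total coverage after subsampling reads.

    For each depth the per-read genome assignments are subsampled without
    replacement ``reps`` times; coverage is recomputed and genomes at
    >= ``threshold`` coverage counted. Returns a (depth, mean_detected,
    mean_total_coverage) table.
    """
    n = len(assignments)
    for d in depths:
        if d < 0 or d > n:
            raise ValueError(f"depth {d} outside [0, {n}]")
    labels = np.array([a if a is not None else "" for a in assignments])
    names = sorted(genome_sizes)
    rows = []
    rng = np.random.default_rng(seed)
    for depth in depths:
        detected, totals = [], []
        for _ in range(reps):
            take = labels[rng.choice(n, size=depth, replace=False)] if depth else np.array([])
            n_det = 0
            total_cov = 0.0
            for g in names:
                cov = coverage(read_length, int((take == g).sum()), genome_sizes[g]) if depth else 0.0
                if cov >= threshold:
                    n_det += 1
                    total_cov += cov
            detected.append(n_det)
            totals.append(total_cov)
        rows.append(
            {
                "depth": depth,
                "mean_detected": float(np.mean(detected)),
                "mean_total_coverage": float(np.mean(totals)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"library", "gotu_id", "n_reads"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts TSV needs columns {sorted(required)}")
    return df


def profiles_from_counts(
    counts: pd.DataFrame,
    genome_sizes: dict[str, float],
    read_length: float,
    threshold: float = BDL_THRESHOLD,
    rounded: bool = False,
) -> list[LibraryProfile]:
    profiles = []
    for library, sub in counts.groupby("library"):
        c = dict(zip(sub["gotu_id"], sub["n_reads"]))
        profiles.append(
            profile_library(
                str(library),
                counts=c,
                genome_sizes=genome_sizes,
                read_length=read_length,
                threshold=threshold,
                rounded=rounded,
            )
        )
    return profiles


def write_profiles_tsv(path, profiles: list[LibraryProfile]) -> None:
    rows = []
    for p in profiles:
        for r in p.records:
            rows.append(
                {
                    "library": p.library,
                    "gotu_id": r.gotu_id,
                    "coverage": r.coverage,
                    "bdl": r.bdl,
                    "rel_abundance_pct": (
                        round_half_up(r.rel_abundance, 2) if r.rel_abundance is not None else ""
                    ),
                    "detection_limit_pct": (
                        round_half_up(p.detection_limit_pct, 2)
                        if p.detection_limit_pct is not None
                        else ""
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
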