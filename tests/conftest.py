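"""Shared fixtures: a frozen four-library worked example and small communities.

The worked example is a report-style coverage table of 11 species-level
genome clusters (gOTU_01..gOTU_11) profiled across one unsorted library (UC)
and three sorted sub-community libraries (DG, LA, OG), together with the
recovery marks saying where each cluster's MAG was actually binned. BDL cells
(coverage below 10x) carry no printed coverage. The frozen percentages are the
report's printed values; two cells whose printed numbers are arithmetically
inconsistent with their own column (the whole UC column and the LA cell of
gOTU_04) are excluded from golden comparisons.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")

GOTUS = [f"gOTU_{i:02d}" for i in range(1, 12)]
LIBRARIES = ["UC", "DG", "LA", "OG"]

# integer fold-coverages; None = below detection limit (no printed value)
WORKED_COVERAGE = {
    "UC": dict(zip(GOTUS, [73, 35, 30, 82, 10, 35, 17, 12, 43, 10, 20])),
    "DG": dict(zip(GOTUS, [147, None, 45, 28, 10, None, None, None, 35, None, None])),
    "LA": dict(zip(GOTUS, [52, 42, 72, 25, None, None, 14, 12, 35, 14, 119])),
    "OG": dict(zip(GOTUS, [103, 22, 89, 41, None, 13, 16, 11, 32, 24, 37])),
}

# printed relative abundances (percent) for the arithmetically consistent cells
WORKED_PERCENT = {
    "DG": dict(
        zip(
            ["gOTU_01", "gOTU_03", "gOTU_04", "gOTU_05", "gOTU_09"],
            [55.47, 16.98, 10.56, 3.77, 13.20],
        )
    ),
    "LA": {
        "gOTU_01": 13.50,
        "gOTU_02": 10.90,
        "gOTU_03": 18.70,
        # gOTU_04 printed 10.56 is inconsistent with its own column; excluded
        "gOTU_07": 3.63,
        "gOTU_08": 3.11,
        "gOTU_09": 9.09,
        "gOTU_10": 3.63,
        "gOTU_11": 30.90,
    },
    "OG": {
        "gOTU_01": 26.54,
        "gOTU_02": 5.67,
        "gOTU_03": 22.93,
        "gOTU_04": 10.56,
        "gOTU_06": 3.35,
        "gOTU_07": 4.12,
        "gOTU_08": 2.83,
        "gOTU_09": 8.24,
        "gOTU_10": 6.18,
        "gOTU_11": 9.53,
    },
}

# printed per-library detection-limit bounds (percent)
WORKED_DL = {"LA": 2.60, "OG": 2.58}

# recovery marks: libraries in which each cluster's MAG was binned
WORKED_RECOVERY = {
    "gOTU_01": ["UC", "DG", "LA", "OG"],
    "gOTU_02": ["UC", "LA", "OG"],
    "gOTU_03": ["UC"],
    "gOTU_04": ["UC"],
    "gOTU_05": ["UC", "LA", "OG"],
    "gOTU_06": ["UC", "LA", "OG"],
    "gOTU_07": ["DG"],
    "gOTU_08": ["LA"],
    "gOTU_09": ["LA"],
    "gOTU_10": ["OG"],
    "gOTU_11": ["UC", "LA", "OG"],
}

# 21-gate worked example: 5 dominant gates totalling 116,796 cells and
# 16 low-abundant gates totalling 44,024, inside a 200,000-cell master gate
WORKED_GATES = {
    # dominant gates (above the 7658.1 mean), spanning the 8646..43129 range
    "G1": 43129,
    "G2": 21674,
    "G3": 21674,
    "G4": 21673,
    "G9": 8646,
    # low-abundant gates (at or below the mean), spanning 500..7311
    "G5": 7311,
    "G6": 500,
    **{f"G{i}": 2587 for i in [7, 8]},
    **{f"G{i}": 2587 for i in range(10, 21)},
    "G21": 2582,
}
WORKED_MASTER = 200_000


@pytest.fixture(scope="session")
def worked_gates():
    counts = dict(WORKED_GATES)
    assert len(counts) == 21
    assert sum(counts.values()) == 160_820
    return counts


@pytest.fixture(scope="session")
def worked_coverage():
    return {lib: dict(cov) for lib, cov in WORKED_COVERAGE.items()}


@pytest.fixture(scope="session")
def worked_percent():
    return WORKED_PERCENT


@pytest.fixture(scope="session")
def worked_recovery_matrix():
    data = {
        lib: [lib in WORKED_RECOVERY[g] for g in GOTUS] for lib in LIBRARIES
    }
    return pd.DataFrame(data, index=GOTUS)


@pytest.fixture(scope="session")
def two_species_spec():
    from cytomag.synthetic import CommunitySpec, SpeciesProfile

    return CommunitySpec(
        species=(
            SpeciesProfile("spA", 50_000, 0.7, event_centroid=(80.0, 120.0)),
            SpeciesProfile("spB", 50_000, 0.3, event_centroid=(160.0, 60.0)),
        ),
        read_length=150,
        seed=11,
    )


def coverages_for_profile(cov: dict) -> dict:
    """Replace BDL cells (None) with 0 fold-coverage for profiling input."""
    return {g: (0.0 if c is None else float(c)) for g, c in cov.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
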