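"""Coverage arithmetic, the 10x detection rule, abundance normalization,
detection limits, pseudo-mapping, and rarefaction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytomag.profiling import (
    KmerIndex,
    coverage,
    profile_library,
    pseudo_map,
    rarefaction_curve,
    summarize_detection_limits,
)
from conftest import coverages_for_profile


class TestCoverage:
    def test_hand_arithmetic(self):
        assert coverage(150, 333_334, 5_000_000) == pytest.approx(10.00002)

    def test_zero_reads(self):
        assert coverage(150, 0, 1_000_000) == 0.0

    def test_linearity(self):
        assert coverage(150, 2_000, 50_000) == 2 * coverage(150, 1_000, 50_000)

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            coverage(150, 10, 0)


class TestDetectionLimitRule:
    def test_boundary_inclusive_at_ten(self):
        profile = profile_library("L", coverages={"a": 10.0, "b": 9.999, "c": 90.0})
        flags = {r.gotu_id: r.bdl for r in profile.records}
        assert flags == {"a": False, "b": True, "c": False}
        assert profile.abundances()["a"] == pytest.approx(10.0)

    def test_all_below_empty_abundances(self):
        profile = profile_library("L", coverages={"a": 1.0, "b": 9.0})
        assert profile.abundances() == {}
        assert profile.detection_limit_pct is None

    def test_single_detected_is_hundred_percent(self):
        profile = profile_library("L", coverages={"a": 50.0, "b": 2.0})
        assert profile.abundances() == {"a": pytest.approx(100.0)}


class TestRelativeAbundance:
    def test_dominant_column(self):
        covs = dict(zip("abcde", [147.0, 45.0, 28.0, 10.0, 35.0]))
        profile = profile_library("DG", coverages=covs)
        expected = {
            "a": 55.47,
            "b": 16.98,
            "c": 10.57,
            "d": 3.77,
            "e": 13.21,
        }
        for g, pct in expected.items():
            assert profile.abundances()[g] == pytest.approx(pct, abs=0.005)

    def test_low_abundant_column_max(self):
        covs = dict(
            zip("abcdefghi", [52.0, 42.0, 72.0, 25.0, 14.0, 12.0, 35.0, 14.0, 119.0])
        )
        profile = profile_library("LA", coverages=covs)
        assert max(profile.abundances().values()) == pytest.approx(30.91, abs=0.005)

    @given(
        st.dictionaries(
            st.text("abcdefgh", min_size=1, max_size=2),
            st.floats(min_value=0, max_value=500, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_normalization_invariant(self, covs):
        profile = profile_library("L", coverages=covs)
        ab = profile.abundances()
        if ab:
            assert sum(ab.values()) == pytest.approx(100.0, abs=0.05)

    def test_scale_invariance(self):
        covs = {"a": 20.0, "b": 40.0, "c": 140.0}
        base = profile_library("L", coverages=covs).abundances()
        scaled = profile_library(
            "L", coverages={g: 3.5 * c for g, c in covs.items()}
        ).abundances()
        for g in covs:
            assert base[g] == pytest.approx(scaled[g])


class TestDetectionLimits:
    @pytest.mark.parametrize(
        "total,expected",
        [(385.0, 2.60), (388.0, 2.58), (1000.0, 1.00)],
    )
    def test_per_library(self, total, expected):
        from cytomag.profiling import detection_limit_pct

        assert detection_limit_pct(total) == pytest.approx(expected, abs=0.005)

    def test_four_library_summary(self):
        profiles = [
            profile_library(lib, coverages={"x": total})
            for lib, total in zip("ABCD", (367.0, 265.0, 385.0, 388.0))
        ]
        mean, sd = summarize_detection_limits(profiles)
        assert round(mean, 2) == 2.92
        assert round(sd, 2) == 0.57

    def test_identical_libraries_zero_sd(self):
        profiles = [profile_library(l, coverages={"x": 500.0}) for l in "AB"]
        mean, sd = summarize_detection_limits(profiles)
        assert sd == 0.0

    def test_two_library_hand_arithmetic(self):
        profiles = [
            profile_library("A", coverages={"x": 500.0}),
            profile_library("B", coverages={"x": 1000.0}),
        ]
        mean, sd = summarize_detection_limits(profiles)
        assert mean == pytest.approx(1.50)
        assert sd == pytest.approx(0.7071, abs=0.001)

    def test_strictly_decreasing_in_total(self):
        from cytomag.profiling import detection_limit_pct

        totals = np.linspace(10, 1000, 25)
        limits = [detection_limit_pct(t) for t in totals]
        assert all(a > b for a, b in zip(limits, limits[1:]))


class TestGoldenTable:
    def test_consistent_cells_reproduced(
        self, worked_coverage, worked_percent
    ):
        """Feeding the report's integer coverages through BDL masking and
        normalization reproduces every arithmetically consistent percentage
        to final-digit rounding (+/-0.011)."""
        for lib in ("DG", "LA", "OG"):
            profile = profile_library(
                lib, coverages=coverages_for_profile(worked_coverage[lib])
            )
            ab = profile.abundances()
            for gotu, printed in worked_percent[lib].items():
                assert ab[gotu] == pytest.approx(printed, abs=0.011), (lib, gotu)

    def test_detection_limit_bounds(self, worked_coverage):
        from conftest import WORKED_DL

        for lib, printed in WORKED_DL.items():
            profile = profile_library(
                lib, coverages=coverages_for_profile(worked_coverage[lib])
            )
            assert profile.detection_limit_pct == pytest.approx(printed, abs=0.005)

    def test_rounded_mode_matches_integer_normalization(self):
        covs = {"a": 146.6, "b": 45.4, "c": 28.1, "d": 10.2, "e": 34.7}
        rounded = profile_library("L", coverages=covs, rounded=True)
        assert rounded.total_above_bdl_coverage == 147 + 45 + 28 + 10 + 35


class TestPseudoMap:
    def test_single_genome_reads_assigned(self, two_species_spec):
        from cytomag.synthetic import generate_genomes, generate_reads

        genomes, _, _ = generate_genomes(two_species_spec)
        reads, _ = generate_reads({"spA": 1.0}, 2_000, two_species_spec, genomes)
        result = pseudo_map(reads, genomes)
        assert result.counts["spA"] >= 0.99 * 2_000
        assert result.counts["spB"] == 0

    def test_all_n_read_unassigned(self, two_species_spec):
        from cytomag.synthetic import generate_genomes

        genomes, _, _ = generate_genomes(two_species_spec)
        result = pseudo_map([("r1", "N" * 150)], genomes)
        assert result.n_unassigned == 1
        assert result.n_assigned == 0

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            KmerIndex({})


class TestRarefaction:
    @staticmethod
    def _assignments():
        # 3 genomes of 10 kb; coverage at full depth: 150*N/10_000
        labels = ["g1"] * 4_000 + ["g2"] * 2_000 + ["g3"] * 800 + [None] * 200
        rng = np.random.default_rng(5)
        rng.shuffle(labels)
        sizes = {"g1": 10_000.0, "g2": 10_000.0, "g3": 5_000.0}
        return labels, sizes

    def test_full_depth_equals_unrarefied(self):
        labels, sizes = self._assignments()
        curve = rarefaction_curve(labels, sizes, 150, [len(labels)], reps=3, seed=1)
        # every genome far above 10x at full depth
        assert curve["mean_detected"].iloc[0] == 3.0

    def test_zero_depth(self):
        labels, sizes = self._assignments()
        curve = rarefaction_curve(labels, sizes, 150, [0], reps=2, seed=1)
        assert curve["mean_detected"].iloc[0] == 0.0

    def test_plateau_before_full_depth(self):
        labels, sizes = self._assignments()
        depths = [500, 2_000, 4_000, 7_000]
        curve = rarefaction_curve(labels, sizes, 150, depths, reps=5, seed=2)
        detected = curve["mean_detected"].tolist()
        assert detected == sorted(detected)
        assert detected[-1] == 3.0  # plateau at the true genome count
        assert detected[-2] == 3.0  # reached before full depth

    def test_depth_beyond_library_rejected(self):
        labels, sizes = self._assignments()
        with pytest.raises(ValueError):
            rarefaction_curve(labels, sizes, 150, [len(labels) + 1], reps=1, seed=1)
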