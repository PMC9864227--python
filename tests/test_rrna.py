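"""16S post-processing: length filter, chimera flag, greedy clustering,
three-step abundance aggregation."""

import numpy as np
import pytest

from cytomag.rrna import (
    FilterPolicy,
    RrnaSequence,
    aggregate_abundance,
    filter_length,
    flag_chimeras,
    greedy_cluster,
    min_abundance_summary,
    run_pipeline,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_gene(length=1200, seed=0):
    rng = np.random.default_rng(seed)
    return BASES[rng.integers(0, 4, length)].tobytes().decode()


def mutate_exact(seq, n_subs, seed):
    """Exactly n_subs substitutions at distinct positions, each to a new base."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in rng.choice(arr.size, n_subs, replace=False):
        arr[p] = rng.choice(BASES[BASES != arr[p]])
    return arr.tobytes().decode()


def seq(seq_id, sequence, library="L1", count=1):
    return RrnaSequence(seq_id=seq_id, library=library, sequence=sequence, count=count)


class TestFilterLength:
    def test_boundary_strict(self):
        short = seq("short", "A" * 899)
        exact = seq("exact", "A" * 900)
        kept, removed = filter_length([short, exact])
        assert [s.seq_id for s in kept] == ["exact"]
        assert [s.seq_id for s in removed] == ["short"]

    def test_empty_input(self):
        assert filter_length([]) == ([], [])

    def test_synthetic_pool_counts(self):
        pool = [seq(f"s{i}", "A" * (800 if i < 10 else 1000)) for i in range(50)]
        kept, removed = filter_length(pool)
        assert len(kept) == 40 and len(removed) == 10


class TestFlagChimeras:
    @staticmethod
    def _refs(n=3, divergence_step=60, length=1200):
        # parents at >= 5% pairwise divergence (60/1200 between neighbours)
        ancestor = random_gene(length, seed=42)
        return {
            f"ref{i}": mutate_exact(ancestor, divergence_step * i, seed=100 + i)
            for i in range(n)
        }

    def test_exact_reference_copy_clean(self):
        refs = self._refs()
        copies = [seq("c0", refs["ref0"]), seq("c1", refs["ref1"])]
        clean, flagged = flag_chimeras(copies, refs)
        assert flagged == []

    def test_two_parent_join_flagged(self):
        refs = self._refs()
        half = 600
        chimera = refs["ref0"][:half] + refs["ref2"][half:]
        clean, flagged = flag_chimeras([seq("chi", chimera)], refs)
        assert [s.seq_id for s in flagged] == ["chi"]

    def test_single_reference_nothing_flagged(self):
        refs = {"only": random_gene(seed=7)}
        copies = [seq("c", refs["only"])]
        clean, flagged = flag_chimeras(copies, refs)
        assert flagged == []

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            flag_chimeras([seq("c", random_gene())], {})

    def test_short_reference_skipped_with_warning(self):
        refs = {"ok": random_gene(seed=1), "stub": "ACGT" * 20}
        with pytest.warns(UserWarning, match="skipped"):
            flag_chimeras([seq("c", refs["ok"])], refs)


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        g = random_gene(seed=3)
        clusters = greedy_cluster([seq("a", g), seq("b", g)])
        assert len(clusters) == 1

    def test_threshold_splits_at_96_joins_at_98(self):
        g = random_gene(seed=4)
        # 48/1200 = 4% divergence -> identity 0.96; 24/1200 -> 0.98
        far = mutate_exact(g, 48, seed=5)
        near = mutate_exact(g, 24, seed=6)
        assert len(greedy_cluster([seq("a", g), seq("b", far)])) == 2
        assert len(greedy_cluster([seq("a", g), seq("b", near)])) == 1

    def test_highest_count_is_centroid(self):
        g = random_gene(seed=8)
        variant = mutate_exact(g, 12, seed=9)
        clusters = greedy_cluster([seq("minor", g, count=3), seq("major", variant, count=10)])
        assert clusters[0].centroid.seq_id == "major"

    def test_membership_certificate(self):
        """Every member re-verifies at >= threshold identity to its centroid."""
        from cytomag.alignment import identity

        g = random_gene(seed=10)
        pool = [seq(f"v{i}", mutate_exact(g, 12 * (i % 3), seed=20 + i), count=5 - i % 3)
                for i in range(6)]
        clusters = greedy_cluster(pool, threshold=0.97)
        for cl in clusters:
            for m in cl.members:
                assert identity(m.sequence, cl.centroid.sequence) >= 0.97

    def test_threshold_monotonicity(self):
        g = random_gene(seed=11)
        pool = [seq(f"v{i}", mutate_exact(g, 18 * i, seed=30 + i)) for i in range(4)]
        n_clusters = [len(greedy_cluster(pool, t)) for t in (0.95, 0.97, 0.99)]
        assert n_clusters == sorted(n_clusters)


class TestAggregate:
    def test_single_sequence_single_library(self):
        s = seq("s1", random_gene(seed=12), library="UC", count=7)
        rotus, report = run_pipeline([s], references=None, policy=FilterPolicy(chimera_check=False))
        assert len(rotus) == 1
        assert rotus[0].abundance == {"UC": pytest.approx(100.0)}

    def test_conservation_within_one_cluster(self):
        g = random_gene(seed=13)
        pool = [
            seq("a", g, count=60),
            seq("b", mutate_exact(g, 12, seed=14), count=30),
            seq("c", mutate_exact(g, 6, seed=15), count=10),
        ]
        rotus, _ = run_pipeline(pool, policy=FilterPolicy(chimera_check=False))
        assert len(rotus) == 1
        assert rotus[0].abundance["L1"] == pytest.approx(100.0)

    def test_shared_and_private_species(self):
        shared = random_gene(seed=16)
        private1 = mutate_exact(shared, 120, seed=17)  # 10% away
        private2 = mutate_exact(shared, 240, seed=18)
        pool = [
            seq("s1", shared, library="A", count=6),
            seq("p1", private1, library="A", count=4),
            seq("s2", shared, library="B", count=3),
            seq("p2", private2, library="B", count=7),
        ]
        rotus, _ = run_pipeline(pool, policy=FilterPolicy(chimera_check=False))
        assert len(rotus) == 3
        by_rep = {r.representative: r for r in rotus}
        shared_rotu = next(r for r in rotus if {"A", "B"} <= set(r.abundance))
        assert shared_rotu.abundance["A"] == pytest.approx(60.0)
        assert shared_rotu.abundance["B"] == pytest.approx(30.0)
        private_rotus = [r for r in rotus if r is not shared_rotu]
        assert {tuple(r.abundance) for r in private_rotus} == {("A",), ("B",)}

    def test_per_library_conservation_invariant(self):
        rng = np.random.default_rng(19)
        ancestor = random_gene(seed=20)
        pool = []
        for lib in ("UC", "DG", "LA"):
            for i in range(4):
                variant = mutate_exact(ancestor, int(rng.integers(0, 90)), seed=300 + i)
                pool.append(seq(f"{lib}_{i}", variant, library=lib, count=int(rng.integers(1, 50))))
        rotus, _ = run_pipeline(pool, policy=FilterPolicy(chimera_check=False))
        for lib in ("UC", "DG", "LA"):
            total = sum(r.abundance.get(lib, 0.0) for r in rotus)
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_missing_secondary_representative_rejected(self):
        g = random_gene(seed=21)
        s = seq("s1", g, library="A", count=1)
        primary = {"A": greedy_cluster([s])}
        with pytest.raises(ValueError, match="secondary"):
            aggregate_abundance({"A": [s]}, primary, secondary=[])

    def test_min_abundance_summary_defined(self):
        shared = random_gene(seed=22)
        pool = [
            seq("a1", shared, library="A", count=9),
            seq("a2", mutate_exact(shared, 120, seed=23), library="A", count=1),
            seq("b1", shared, library="B", count=4),
            seq("b2", mutate_exact(shared, 120, seed=23), library="B", count=1),
        ]
        rotus, _ = run_pipeline(pool, policy=FilterPolicy(chimera_check=False))
        mean, sd = min_abundance_summary(rotus)
        assert mean == pytest.approx((10.0 + 20.0) / 2)
        assert sd is not None
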