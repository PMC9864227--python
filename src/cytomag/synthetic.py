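"""Synthetic multi-species communities with known ground truth.

Emulates the data a sorted-metagenomics experiment produces: a community of
species with a log-scale abundance spread, per-species event clouds in a
DAPI x forward-scatter plane, shotgun reads with substitution errors drawn
from the genomes, and near-full-length 16S genes at controlled pairwise
divergence, optionally contaminated with two-parent chimeras. Every generator
is a pure function of its spec and seed, so downstream stages can be tested
against exact truth without any external data.

Genomes are i.i.d. uniform nucleotide sequences (no downstream stage assumes
genomic realism); 16S genes are mutated copies of a single community ancestor,
which makes pairwise identities controllable; event clouds are independent
bivariate normals per species.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def subseed(master: int, stage: str, label: str = "") -> int:
    """Stable sub-seed derived by hashing (master, stage, label)."""
    digest = hashlib.sha256(f"{master}:{stage}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SpeciesProfile:
    """One community member: genome size, abundance and cytometric signature.

    ``rrna_divergence`` is the percent divergence of the species' 16S gene
    from the community ancestor gene; the pairwise divergence between two
    species is approximately the sum of their divergences from the ancestor.
    """

    species_id: str
    genome_length: int
    abundance_weight: float
    event_centroid: tuple[float, float] = (100.0, 100.0)  # (fsc, dapi)
    event_spread: tuple[float, float] = (10.0, 10.0)
    rrna_divergence: float = 0.0


@dataclass(frozen=True)
class CommunitySpec:
    """Full description of a synthetic community and its sequencing run."""

    species: tuple[SpeciesProfile, ...]
    total_events: int = 200_000
    read_length: int = 150
    substitution_rate: float = 0.0
    chimera_rate: float = 0.0
    seed: int = 0
    rrna_length: int = 1500

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if self.total_events <= 0:
            raise ValueError("total_events must be positive")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be in [0, 1]")
        if self.rrna_length < 1200:
            raise ValueError("rrna_length must be >= 1200 (near full length)")
        seen = set()
        for sp in self.species:
            if sp.species_id in seen:
                raise ValueError(f"duplicate species_id {sp.species_id!r}")
            seen.add(sp.species_id)
            if sp.genome_length < 10 * self.read_length:
                raise ValueError(
                    f"species {sp.species_id!r}: genome_length must be >= 10x read length"
                )
            if sp.abundance_weight <= 0:
                raise ValueError(
                    f"species {sp.species_id!r}: abundance_weight must be positive"
                )
            if sp.event_spread[0] <= 0 or sp.event_spread[1] <= 0:
                raise ValueError(
                    f"species {sp.species_id!r}: event spreads must be positive"
                )
            if sp.rrna_divergence < 0:
                raise ValueError(
                    f"species {sp.species_id!r}: rrna_divergence must be >= 0"
                )
        total = sum(sp.abundance_weight for sp in self.species)
        if self.species and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundance weights sum to {total!r}, expected 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([sp.abundance_weight for sp in self.species])

    @property
    def species_ids(self) -> list[str]:
        return [sp.species_id for sp in self.species]


@dataclass
class GroundTruth:
    """What the generators actually did: per-library composition and chimera ids."""

    compositions: dict[str, dict[str, float]] = field(default_factory=dict)
    chimera_ids: set[str] = field(default_factory=set)
    chimera_parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add_composition(self, library: str, fractions: dict[str, float]) -> None:
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"library {library!r}: fractions sum to {total!r}")
        self.compositions[library] = dict(fractions)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions to a different base."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if n_subs == 0:
        return seq
    pos = rng.choice(arr.size, size=n_subs, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def generate_genomes(
    spec: CommunitySpec,
) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Per-species genomes and 16S genes, plus an (initially empty) truth record.

    Each species' 16S gene is the community ancestor mutated at exactly
    ``round(rrna_divergence/100 * rrna_length)`` positions, so realized
    pairwise divergences track the configured values.
    """
    if not spec.species:
        raise ValueError("community has no species")
    genomes: dict[str, str] = {}
    rrna: dict[str, str] = {}
    ancestor_rng = np.random.default_rng(subseed(spec.seed, "rrna-ancestor"))
    ancestor = _random_sequence(ancestor_rng, spec.rrna_length)
    for sp in spec.species:
        g_rng = np.random.default_rng(subseed(spec.seed, "genome", sp.species_id))
        genomes[sp.species_id] = _random_sequence(g_rng, sp.genome_length)
        r_rng = np.random.default_rng(subseed(spec.seed, "rrna", sp.species_id))
        n_subs = int(round(sp.rrna_divergence / 100.0 * spec.rrna_length))
        rrna[sp.species_id] = _mutate(r_rng, ancestor, n_subs)
    return genomes, rrna, GroundTruth()


def generate_events(spec: CommunitySpec) -> pd.DataFrame:
    """Cytometric event table with columns (fsc, dapi, species).

    Species counts are multinomial around the abundance weights; each species'
    cloud is an axis-aligned bivariate normal around its centroid.
    """
    if not spec.species:
        raise ValueError("community has no species")
    rng = np.random.default_rng(subseed(spec.seed, "events"))
    counts = rng.multinomial(spec.total_events, spec.weights)
    fsc, dapi, labels = [], [], []
    for sp, n in zip(spec.species, counts):
        fsc.append(rng.normal(sp.event_centroid[0], sp.event_spread[0], n))
        dapi.append(rng.normal(sp.event_centroid[1], sp.event_spread[1], n))
        labels.extend([sp.species_id] * int(n))
    df = pd.DataFrame(
        {
            "fsc": np.concatenate(fsc),
            "dapi": np.concatenate(dapi),
            "species": labels,
        }
    )
    return df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


def generate_reads(
    composition: dict[str, float],
    depth: int,
    spec: CommunitySpec,
    genomes: dict[str, str],
    library: str = "lib",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Single-end reads of fixed length from the genomes, with known origin.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)`` pairs
    and truth records (read_id, species, start, strand, n_errors). Reads are
    drawn uniformly along each genome, reverse-complemented with probability
    0.5, and carry i.i.d. substitution errors at ``spec.substitution_rate``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition fractions sum to {total!r}, expected 1")
    missing = set(composition) - set(genomes)
    if missing:
        raise ValueError(f"composition names unknown species: {sorted(missing)}")
    rng = np.random.default_rng(subseed(spec.seed, "reads", library))
    species = sorted(composition)
    fracs = np.array([composition[s] for s in species])
    counts = rng.multinomial(depth, fracs) if depth else np.zeros(len(species), int)
    L = spec.read_length
    reads: list[tuple[str, str]] = []
    rows = []
    for sp_id, n in zip(species, counts):
        genome = genomes[sp_id]
        starts = rng.integers(0, len(genome) - L + 1, n)
        flips = rng.random(n) < 0.5
        for i, (start, flip) in enumerate(zip(starts, flips)):
            frag = genome[start : start + L]
            if flip:
                frag = reverse_complement(frag)
            n_err = 0
            if spec.substitution_rate > 0:
                err_pos = np.nonzero(rng.random(L) < spec.substitution_rate)[0]
                n_err = err_pos.size
                if n_err:
                    arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
                    for p in err_pos:
                        arr[p] = rng.choice(_BASES[_BASES != arr[p]])
                    frag = arr.tobytes().decode("ascii")
            read_id = f"{library}|{sp_id}|{start}|{'-' if flip else '+'}|{i}"
            reads.append((read_id, frag))
            rows.append((read_id, sp_id, int(start), "-" if flip else "+", n_err))
    truth = pd.DataFrame(
        rows, columns=["read_id", "species", "start", "strand", "n_errors"]
    )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = truth.iloc[order].reset_index(drop=True)
    return reads, truth


@dataclass(frozen=True)
class RrnaCopy:
    """One emitted 16S copy: its id, source species (or chimera parents), sequence."""

    copy_id: str
    species: str
    sequence: str


def sample_rrna_pool(
    spec: CommunitySpec,
    rrna: dict[str, str],
    n_copies: int,
    library: str = "lib",
) -> list[RrnaCopy]:
    """Multinomial sample of 16S copies by abundance weight."""
    rng = np.random.default_rng(subseed(spec.seed, "rrna-pool", library))
    counts = rng.multinomial(n_copies, spec.weights)
    pool = []
    for sp, n in zip(spec.species, counts):
        for i in range(int(n)):
            pool.append(
                RrnaCopy(f"{library}|{sp.species_id}|{i}", sp.species_id, rrna[sp.species_id])
            )
    return pool


def inject_chimeras(
    pool: list[RrnaCopy],
    rate: float,
    seed: int,
    rrna: dict[str, str] | None = None,
) -> tuple[list[RrnaCopy], GroundTruth]:
    """Replace a ``rate`` fraction of 16S copies with two-parent chimeras.

    A chimera is the left half of one parent gene joined to the right half of
    a different parent. Parents default to the distinct species present in the
    pool; pass ``rrna`` to widen the parent set. Labels land in the returned
    GroundTruth.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    parents = dict(rrna) if rrna else {c.species: c.sequence for c in pool}
    if rate > 0 and len(parents) < 2:
        raise ValueError("chimera injection needs at least 2 parent species")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    out: list[RrnaCopy] = []
    parent_ids = sorted(parents)
    for copy in pool:
        if rate > 0 and rng.random() < rate:
            a, b = rng.choice(len(parent_ids), size=2, replace=False)
            pa, pb = parent_ids[a], parent_ids[b]
            left = parents[pa]
            right = parents[pb]
            half = len(left) // 2
            seq = left[:half] + right[half:]
            cid = f"{copy.copy_id}|chimera"
            out.append(RrnaCopy(cid, f"{pa}x{pb}", seq))
            truth.chimera_ids.add(cid)
            truth.chimera_parents[cid] = (pa, pb)
        else:
            out.append(copy)
    return out, truth


def write_fasta(path, records: dict[str, str] | list[tuple[str, str]]) -> None:
    """Write sequences as FASTA (60-column wrap), deterministically ordered."""
    items = sorted(records.items()) if isinstance(records, dict) else list(records)
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_fastq(path, reads: list[tuple[str, str]], quality: str = "I") -> None:
    """Write reads as FASTQ with constant Phred+33 quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")
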