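"""Post-processing of reconstructed 16S rRNA genes into rOTUs.

The pipeline takes near-full-length 16S sequences reconstructed per library
(each with a supporting read count) and:

1. drops sequences shorter than 900 bp (too short for species-level identity);
2. flags likely two-parent chimeras against a reference set: a sequence is
   chimeric when the best-matching reference differs between its left and
   right half and each half beats the full-length best identity by at least
   2 percentage points;
3. clusters the retained sequences greedily at 97% identity per library
   (primary clustering), processing in decreasing count order;
4. pools the primary centroids across libraries and clusters them again at
   97% (secondary clustering), yielding the final rOTUs;
5. aggregates abundances in three steps — per-sequence count fractions per
   library, summed within primary clusters, then summed within each rOTU —
   so every library's final rOTU abundances total 100%.

Identity everywhere is the package's fixed global-alignment definition
(:mod:`cytomag.alignment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment import identity
from ._util import round_half_up

MIN_LENGTH = 900
CLUSTER_IDENTITY = 0.97
CHIMERA_MARGIN_PP = 2.0


@dataclass
class RrnaSequence:
    """One reconstructed 16S sequence with its library and read support."""

    seq_id: str
    library: str
    sequence: str
    count: int = 1
    rel_abundance: float | None = None
    species_label: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterPolicy:
    min_length: int = MIN_LENGTH
    cluster_identity: float = CLUSTER_IDENTITY
    chimera_check: bool = True

    def __post_init__(self):
        if not 0.0 < self.cluster_identity <= 1.0:
            raise ValueError("cluster_identity must be in (0, 1]")


@dataclass
class Cluster:
    """A greedy cluster: its centroid sequence and all members (incl. centroid)."""

    centroid: RrnaSequence
    members: list[RrnaSequence] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(m.count for m in self.members)


@dataclass
class RotuCluster:
    """A final rOTU with library-resolved relative abundances (percent)."""

    rotu_id: str
    members: list[tuple[str, str]]  # (seq_id, library)
    representative: str
    abundance: dict[str, float] = field(default_factory=dict)
    species_label: str = ""


def filter_length(
    sequences: list[RrnaSequence], min_length: int = MIN_LENGTH
) -> tuple[list[RrnaSequence], list[RrnaSequence]]:
    """Retain sequences of at least ``min_length`` bases (900 bp is kept)."""
    retained = [s for s in sequences if s.length >= min_length]
    removed = [s for s in sequences if s.length < min_length]
    return retained, removed


def flag_chimeras(
    sequences: list[RrnaSequence],
    references: dict[str, str],
    margin_pp: float = CHIMERA_MARGIN_PP,
) -> tuple[list[RrnaSequence], list[RrnaSequence]]:
    """Two-segment best-parent chimera test against a reference set.

    A sequence is flagged when its left and right halves have different
    best-matching references and each half's identity exceeds the best
    full-length identity by at least ``margin_pp`` percentage points.
    References shorter than the half-window are skipped with a warning.
    """
    if not references:
        raise ValueError("reference set is empty")
    clean, flagged = [], []
    for seq in sequences:
        half = seq.length // 2
        usable = {rid: r for rid, r in references.items() if len(r) >= half}
        skipped = set(references) - set(usable)
        if skipped:
            import warnings

            warnings.warn(
                f"references shorter than the half-length window skipped: {sorted(skipped)}"
            )
        if not usable:
            clean.append(seq)
            continue
        _, full_best = _best(seq.sequence, usable)
        left_id, left_best = _best(seq.sequence[:half], usable)
        right_id, right_best = _best(seq.sequence[half:], usable)
        is_chimera = (
            left_id != right_id
            and (left_best - full_best) * 100.0 >= margin_pp
            and (right_best - full_best) * 100.0 >= margin_pp
        )
        (flagged if is_chimera else clean).append(seq)
    return clean, flagged


def _best(query: str, references: dict[str, str]) -> tuple[str, float]:
    best_id, best = None, -1.0
    for rid in sorted(references):
        ident = identity(query, references[rid])
        if ident > best:
            best_id, best = rid, ident
    return best_id, best


def greedy_cluster(
    sequences: list[RrnaSequence], threshold: float = CLUSTER_IDENTITY
) -> list[Cluster]:
    """Greedy centroid clustering at ``threshold`` identity.

    Sequences are processed in decreasing count order (ties: longer first,
    then smallest id); each joins the first existing centroid it matches at
    >= threshold, else founds a new cluster. Every member therefore has
    identity >= threshold to its centroid.
    """
    ordered = sorted(sequences, key=lambda s: (-s.count, -s.length, s.seq_id))
    clusters: list[Cluster] = []
    for seq in ordered:
        for cl in clusters:
            if identity(seq.sequence, cl.centroid.sequence) >= threshold:
                cl.members.append(seq)
                break
        else:
            clusters.append(Cluster(centroid=seq, members=[seq]))
    return clusters


def aggregate_abundance(
    sequences_by_library: dict[str, list[RrnaSequence]],
    primary: dict[str, list[Cluster]],
    secondary: list[Cluster],
) -> list[RotuCluster]:
    """Three-step abundance aggregation into final rOTUs.

    Step 1: each sequence's count over its library's total count.
    Step 2: sums within each library's primary clusters.
    Step 3: each primary centroid maps into a secondary cluster; primary-cluster
    sums are added per library, giving every rOTU a library-resolved vector.
    """
    # step 1: per-sequence fractions
    step1: dict[str, dict[str, float]] = {}
    for library, seqs in sequences_by_library.items():
        total = sum(s.count for s in seqs)
        if total <= 0:
            raise ValueError(f"library {library!r} has no counted sequences")
        step1[library] = {s.seq_id: s.count / total for s in seqs}
        for s in seqs:
            s.rel_abundance = 100.0 * s.count / total
    # step 2: primary-cluster sums per library
    step2: dict[tuple[str, str], float] = {}  # (library, centroid seq_id) -> fraction
    for library, clusters in primary.items():
        for cl in clusters:
            step2[(library, cl.centroid.seq_id)] = sum(
                step1[library][m.seq_id] for m in cl.members
            )
    # step 3: fold primary clusters into secondary clusters
    known_reps = {m.seq_id for cl in secondary for m in cl.members}
    for library, cid in step2:
        if cid not in known_reps:
            raise ValueError(
                f"primary representative {cid!r} missing from secondary clustering input"
            )
    primary_members: dict[str, list[tuple[str, str]]] = {}
    for library, clusters in primary.items():
        for cl in clusters:
            primary_members[cl.centroid.seq_id] = [
                (m.seq_id, library) for m in cl.members
            ]
    rotus: list[RotuCluster] = []
    for cl in secondary:
        abundance: dict[str, float] = {}
        members: list[tuple[str, str]] = []
        for rep in cl.members:
            members.extend(primary_members.get(rep.seq_id, [(rep.seq_id, rep.library)]))
            for (library, cid), frac in step2.items():
                if cid == rep.seq_id:
                    abundance[library] = abundance.get(library, 0.0) + 100.0 * frac
        rotus.append(
            RotuCluster(
                rotu_id="",
                members=members,
                representative=cl.centroid.seq_id,
                abundance=abundance,
                species_label=cl.centroid.species_label,
            )
        )
    rotus.sort(key=lambda r: (-sum(r.abundance.values()), r.representative))
    for i, r in enumerate(rotus, start=1):
        r.rotu_id = f"rOTU_{i:02d}"
    return rotus


def run_pipeline(
    sequences: list[RrnaSequence],
    references: dict[str, str] | None = None,
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[list[RotuCluster], dict]:
    """Length filter, optional chimera flagging, two-stage clustering, aggregation.

    Returns the final rOTUs and a report dict with the filtered/flagged ids.
    """
    retained, removed = filter_length(sequences, policy.min_length)
    flagged: list[RrnaSequence] = []
    if policy.chimera_check:
        if references is None:
            raise ValueError("chimera_check requires a reference set")
        retained, flagged = flag_chimeras(retained, references)
    by_library: dict[str, list[RrnaSequence]] = {}
    for s in retained:
        by_library.setdefault(s.library, []).append(s)
    primary = {
        lib: greedy_cluster(seqs, policy.cluster_identity)
        for lib, seqs in sorted(by_library.items())
    }
    pooled_reps = [
        RrnaSequence(
            seq_id=cl.centroid.seq_id,
            library=lib,
            sequence=cl.centroid.sequence,
            count=cl.total_count,
            species_label=cl.centroid.species_label,
        )
        for lib, clusters in sorted(primary.items())
        for cl in clusters
    ]
    secondary = greedy_cluster(pooled_reps, policy.cluster_identity)
    rotus = aggregate_abundance(by_library, primary, secondary)
    report = {
        "n_input": len(sequences),
        "removed_short": [s.seq_id for s in removed],
        "flagged_chimeras": [s.seq_id for s in flagged],
        "n_primary_clusters": {lib: len(cls) for lib, cls in primary.items()},
        "n_rotus": len(rotus),
    }
    return rotus, report


def min_abundance_summary(rotus: list[RotuCluster]) -> tuple[float, float | None]:
    """Mean (and n-1 sd) over libraries of the smallest observed rOTU abundance."""
    from ._util import mean_sd

    minima: dict[str, float] = {}
    for r in rotus:
        for lib, pct in r.abundance.items():
            if lib not in minima or pct < minima[lib]:
                minima[lib] = pct
    if not minima:
        raise ValueError("no rOTU abundances present")
    return mean_sd(minima.values())


def read_fasta_with_counts(path, library: str) -> list[RrnaSequence]:
    """Read a FASTA whose headers carry counts via the ``;size=N`` convention."""
    from Bio import SeqIO

    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        name = rec.id
        if ";size=" in rec.description:
            head = rec.description.split(";size=")
            name = head[0].split()[-1] or rec.id
            count = int(head[1].rstrip(";").split(";")[0])
        seqs.append(
            RrnaSequence(seq_id=name, library=library, sequence=str(rec.seq), count=count)
        )
    return seqs


def write_rotus_tsv(path, rotus: list[RotuCluster]) -> None:
    rows = []
    for r in rotus:
        for lib, pct in sorted(r.abundance.items()):
            rows.append(
                {
                    "rotu_id": r.rotu_id,
                    "representative": r.representative,
                    "library": lib,
                    "rel_abundance_pct": round_half_up(pct, 2),
                    "species_label": r.species_label,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
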