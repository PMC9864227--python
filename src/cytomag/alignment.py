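"""Global nucleotide alignment and percent identity.

Identity is defined as matches divided by alignment columns, counting internal
gap columns but not terminal overhangs. Terminal gaps are score-free, so two
sequences of unequal length are compared over their aligned core. The scoring
scheme (match 1, mismatch -1, gap open -2, gap extend -1) is fixed: every
identity threshold in the package (97% rOTU clustering, chimera margins,
divergence checks) refers to this one definition.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    # terminal gaps are free
    a.end_insertion_score = 0.0
    a.end_deletion_score = 0.0
    return a


def identity(a: str, b: str) -> float:
    """Fractional identity (0..1) of the best global alignment of ``a``, ``b``."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner().align(a, b)[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += te - ts
        matches += sum(x == y for x, y in zip(a[ts:te], b[qs:qe]))
    for i in range(len(t_blocks) - 1):
        columns += t_blocks[i + 1][0] - t_blocks[i][1]
        columns += q_blocks[i + 1][0] - q_blocks[i][1]
    return matches / columns if columns else 0.0


def percent_divergence(a: str, b: str) -> float:
    """100 * (1 - identity): the alignment-based divergence in percent."""
    return 100.0 * (1.0 - identity(a, b))


def best_match(query: str, references: dict[str, str]) -> tuple[str, float]:
    """Reference id with the highest identity to ``query`` and that identity.

    Ties break toward the lexicographically smallest reference id.
    """
    if not references:
        raise ValueError("reference set is empty")
    best_id, best_ident = None, -1.0
    for ref_id in sorted(references):
        ident = identity(query, references[ref_id])
        if ident > best_ident:
            best_id, best_ident = ref_id, ident
    return best_id, best_ident
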