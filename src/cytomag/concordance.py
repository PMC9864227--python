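"""Cross-tabulation of gOTU and rOTU detections across libraries.

Builds aligned taxon x library flag matrices for genome-derived (gOTU) and
16S-derived (rOTU) detections, summarizes sharing between the unsorted
control library and the sorted sub-communities (the Venn counts), and
computes the sorted-vs-unsorted resolution ratio and read-mapping summaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from ._util import mean_sd, round_half_up


def canonical_taxon(label: str) -> str:
    """Trim, collapse whitespace, strip italics markup from a taxon label.

    Underscores are markup only at token edges (``_Genus_``), never inside
    identifiers like ``gOTU_01``.
    """
    tokens = [t.strip("_") for t in label.replace("*", "").split()]
    return " ".join(t for t in tokens if t)


@dataclass
class ConcordanceMatrix:
    """Aligned taxon x library boolean tables for gOTU and rOTU evidence."""

    taxa: list[str]
    libraries: list[str]
    gotu_recovered: pd.DataFrame
    gotu_above_dl: pd.DataFrame
    rotu_present: pd.DataFrame
    rotu_above_dl: pd.DataFrame
    notes: list[str]


@dataclass(frozen=True)
class SharingSummary:
    """Venn counts of taxa between the unsorted library and sorted libraries."""

    n_uc_only: int
    n_sorted_only: int
    n_shared: int
    n_in_all: int


def build_matrix(
    gotu_recovered: pd.DataFrame,
    gotu_coverage: pd.DataFrame | None = None,
    rotu_abundance: pd.DataFrame | None = None,
    gotu_taxa: dict[str, str] | None = None,
    rotu_taxa: dict[str, str] | None = None,
    rotu_detection_limit: float = 0.0,
    coverage_threshold: float = 10.0,
) -> ConcordanceMatrix:
    """Align gOTU and rOTU evidence on shared taxon labels.

    ``gotu_recovered`` is a boolean gOTU x library table of where each MAG
    cluster was binned; ``gotu_coverage`` the matching coverage table;
    ``rotu_abundance`` an rOTU x library percent table. The taxon maps
    translate row ids to labels (after canonicalization); rows without a
    counterpart keep an all-False counterpart row. Two gOTUs mapping to one
    taxon label is an error.
    """
    gotu_taxa = {k: canonical_taxon(v) for k, v in (gotu_taxa or {}).items()}
    rotu_taxa = {k: canonical_taxon(v) for k, v in (rotu_taxa or {}).items()}
    notes: list[str] = []

    def taxon_of(row_id: str, mapping: dict[str, str]) -> str:
        return mapping.get(row_id, canonical_taxon(str(row_id)))

    g_labels = [taxon_of(g, gotu_taxa) for g in gotu_recovered.index]
    dupes = {t for t in g_labels if g_labels.count(t) > 1}
    if dupes:
        raise ValueError(f"taxon label(s) mapped to multiple gOTUs: {sorted(dupes)}")
    libraries = list(gotu_recovered.columns)
    r_abund = rotu_abundance if rotu_abundance is not None else pd.DataFrame(columns=libraries)
    r_labels = [taxon_of(r, rotu_taxa) for r in r_abund.index]
    taxa = sorted(set(g_labels) | set(r_labels))

    def empty() -> pd.DataFrame:
        return pd.DataFrame(False, index=taxa, columns=libraries)

    g_rec, g_dl, r_pres, r_dl = empty(), empty(), empty(), empty()
    for g, label in zip(gotu_recovered.index, g_labels):
        g_rec.loc[label] = gotu_recovered.loc[g].astype(bool).values
        if gotu_coverage is not None and g in gotu_coverage.index:
            g_dl.loc[label] = (gotu_coverage.loc[g] >= coverage_threshold).values
    for r, label in zip(r_abund.index, r_labels):
        present = r_abund.loc[r].fillna(0.0) > 0.0
        r_pres.loc[label] = r_pres.loc[label] | present.values
        above = r_abund.loc[r].fillna(0.0) >= rotu_detection_limit
        r_dl.loc[label] = r_dl.loc[label] | (present & above).values
    only_g = set(g_labels) - set(r_labels)
    only_r = set(r_labels) - set(g_labels)
    if only_g:
        notes.append(f"taxa with genome evidence only: {sorted(only_g)}")
    if only_r:
        notes.append(f"taxa with 16S evidence only: {sorted(only_r)}")
    return ConcordanceMatrix(
        taxa=taxa,
        libraries=libraries,
        gotu_recovered=g_rec,
        gotu_above_dl=g_dl,
        rotu_present=r_pres,
        rotu_above_dl=r_dl,
        notes=notes,
    )


def sharing_summary(matrix: ConcordanceMatrix, unsorted: str = "UC") -> SharingSummary:
    """Venn counts over taxa with any gOTU recovery.

    ``n_shared`` counts taxa recovered in the unsorted library and at least
    one sorted library; ``n_in_all`` those recovered everywhere.
    """
    rec = matrix.gotu_recovered
    if unsorted not in rec.columns:
        raise ValueError(f"unsorted library {unsorted!r} not in matrix")
    sorted_libs = [c for c in rec.columns if c != unsorted]
    in_uc = rec[unsorted]
    in_sorted = rec[sorted_libs].any(axis=1)
    return SharingSummary(
        n_uc_only=int((in_uc & ~in_sorted).sum()),
        n_sorted_only=int((~in_uc & in_sorted).sum()),
        n_shared=int((in_uc & in_sorted).sum()),
        n_in_all=(
            int((in_uc & rec[sorted_libs].all(axis=1)).sum())
            if sorted_libs
            else int(in_uc.sum())
        ),
    )


def resolution_ratio(n_sorted: int, n_unsorted: int) -> float | None:
    """Sorted over unsorted recovery count; None when undefined."""
    if n_unsorted < 0 or n_sorted < 0:
        raise ValueError("counts must be >= 0")
    if n_unsorted == 0:
        return None
    return n_sorted / n_unsorted


def mapped_fraction(
    assigned: dict[str, int], totals: dict[str, int]
) -> tuple[dict[str, float], float, float | None]:
    """Percent of reads mapped per library, plus mean +/- sd of the unmapped share.

    The sd is the sample (n-1) standard deviation, absent for one library.
    """
    if set(assigned) != set(totals):
        raise ValueError("assigned and totals must cover the same libraries")
    pct = {}
    for lib in sorted(assigned):
        if totals[lib] <= 0:
            raise ValueError(f"library {lib!r}: total reads must be positive")
        if assigned[lib] > totals[lib]:
            raise ValueError(f"library {lib!r}: assigned exceeds total")
        pct[lib] = 100.0 * assigned[lib] / totals[lib]
    mean_unmapped, sd_unmapped = unmapped_summary(list(pct.values()))
    return pct, mean_unmapped, sd_unmapped


def unmapped_summary(mapped_pct: list[float]) -> tuple[float, float | None]:
    """Mean and sample sd of ``100 - mapped`` across libraries."""
    return mean_sd([100.0 - p for p in mapped_pct])


def format_report(
    matrix: ConcordanceMatrix,
    summary: SharingSummary,
    ratio_mags: float | None = None,
    ratio_taxa: float | None = None,
) -> str:
    lines = ["# gOTU / rOTU concordance report", ""]
    lines.append(f"Taxa: {len(matrix.taxa)}; libraries: {', '.join(matrix.libraries)}")
    lines.append("")
    lines.append("## Sharing (genome recovery)")
    lines.append(f"unsorted-only taxa:        {summary.n_uc_only}")
    lines.append(f"sorted-only taxa:          {summary.n_sorted_only}")
    lines.append(f"shared (UC + >=1 sorted):  {summary.n_shared}")
    lines.append(f"recovered in all libraries: {summary.n_in_all}")
    if ratio_mags is not None:
        lines.append(f"resolution ratio (MAG counts):   {round_half_up(ratio_mags, 2)}")
    if ratio_taxa is not None:
        lines.append(f"resolution ratio (taxon counts): {round_half_up(ratio_taxa, 2)}")
    if matrix.notes:
        lines.append("")
        lines.append("## Notes")
        lines.extend(f"- {n}" for n in matrix.notes)
    return "\n".join(lines) + "\n"
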