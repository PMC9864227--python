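"""Cytometric gate counting, DG/LA/OG partitioning, and sort logistics.

A community measured on a DAPI x forward-scatter plane is covered by a master
cell gate inside which sorting gates are drawn. Gates whose cell counts exceed
the average count per gate form the dominant (DG) sub-community; the rest form
the low-abundant (LA) sub-community; events inside the master gate but outside
every sorting gate are the outer (OG) sub-community, so
``OG = master - (DG + LA)``.

Gates here are axis-aligned rectangles with half-open bounds ``[low, high)``
on both axes: an event on a gate's lower boundary is inside, on the upper
boundary outside. The mean is computed over gated cells only (OG excluded)
and carried at full precision; display rounds half-up to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up


@dataclass(frozen=True)
class Gate:
    """Axis-aligned rectangular sorting gate with half-open bounds."""

    gate_id: str
    fsc_low: float
    fsc_high: float
    dapi_low: float
    dapi_high: float

    def __post_init__(self):
        if self.fsc_low >= self.fsc_high or self.dapi_low >= self.dapi_high:
            raise ValueError(f"gate {self.gate_id!r}: bounds must satisfy low < high")

    def overlaps(self, other: "Gate") -> bool:
        return (
            self.fsc_low < other.fsc_high
            and other.fsc_low < self.fsc_high
            and self.dapi_low < other.dapi_high
            and other.dapi_low < self.dapi_high
        )


@dataclass(frozen=True)
class GatePartition:
    """DG/LA assignment of the sorting gates plus conserved cell totals."""

    dg_gates: tuple[str, ...]
    la_gates: tuple[str, ...]
    mean_cells_per_gate: float
    dg_cells: int
    la_cells: int
    og_cells: int
    master_cells: int

    @property
    def mean_display(self) -> float:
        """The per-gate mean rounded half-up to 1 decimal for reporting."""
        return round_half_up(self.mean_cells_per_gate, 1)


@dataclass(frozen=True)
class SortPlan:
    """Tube arithmetic for sorting a target number of cells."""

    target_cells: float
    per_tube_max: float
    tubes_needed: int
    target_dna_ng: float | None = None


def count_gate_events(events: pd.DataFrame, gates: list[Gate]) -> dict[str, int]:
    """Events per gate under the half-open rectangle convention.

    Gates must be non-overlapping so each event lands in at most one gate.
    """
    ids = [g.gate_id for g in gates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gate ids")
    for i, a in enumerate(gates):
        for b in gates[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(
                    f"gates {a.gate_id!r} and {b.gate_id!r} overlap: ambiguous assignment"
                )
    counts = {}
    fsc = events["fsc"]
    dapi = events["dapi"]
    for g in gates:
        inside = (
            (fsc >= g.fsc_low)
            & (fsc < g.fsc_high)
            & (dapi >= g.dapi_low)
            & (dapi < g.dapi_high)
        )
        counts[g.gate_id] = int(inside.sum())
    return counts


def mean_cells_per_gate(gate_counts: dict[str, int]) -> float:
    """Arithmetic mean of per-gate cell counts (full precision)."""
    if not gate_counts:
        raise ValueError("need at least one gate")
    return sum(gate_counts.values()) / len(gate_counts)


def classify_gates(gate_counts: dict[str, int], master_cells: int) -> GatePartition:
    """Split gates into DG (count > mean) and LA (count <= mean).

    A gate exactly at the mean goes to LA: dominance requires a count strictly
    above the average. OG cells are whatever the master gate holds beyond the
    sorting gates.
    """
    mean = mean_cells_per_gate(gate_counts)
    dg = tuple(sorted(g for g, c in gate_counts.items() if c > mean))
    la = tuple(sorted(g for g, c in gate_counts.items() if c <= mean))
    dg_cells = sum(gate_counts[g] for g in dg)
    la_cells = sum(gate_counts[g] for g in la)
    og_cells = outer_count(master_cells, dg_cells, la_cells)
    return GatePartition(
        dg_gates=dg,
        la_gates=la,
        mean_cells_per_gate=mean,
        dg_cells=dg_cells,
        la_cells=la_cells,
        og_cells=og_cells,
        master_cells=master_cells,
    )


def outer_count(master_cells: int, dg_cells: int, la_cells: int) -> int:
    """OG = master - (DG + LA)."""
    if dg_cells + la_cells > master_cells:
        raise ValueError(
            f"gated cells ({dg_cells + la_cells}) exceed the master gate ({master_cells})"
        )
    return master_cells - dg_cells - la_cells


def plan_sort(
    target_cells: float, per_tube_max: float, target_dna_ng: float | None = None
) -> SortPlan:
    """Smallest number of tubes whose pooled capacity reaches the target."""
    if target_cells <= 0 or per_tube_max <= 0:
        raise ValueError("target_cells and per_tube_max must be positive")
    # round to absorb float noise in exact-multiple inputs like 4.95e7 / 2.25e6
    tubes = math.ceil(round(target_cells / per_tube_max, 9))
    return SortPlan(
        target_cells=target_cells,
        per_tube_max=per_tube_max,
        tubes_needed=tubes,
        target_dna_ng=target_dna_ng,
    )


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"fsc", "dapi"}.issubset(df.columns):
        raise ValueError("events TSV needs 'fsc' and 'dapi' columns")
    return df


def read_gates_tsv(path) -> list[Gate]:
    df = pd.read_csv(path, sep="\t")
    required = {"gate_id", "fsc_low", "fsc_high", "dapi_low", "dapi_high"}
    if not required.issubset(df.columns):
        raise ValueError(f"gates TSV needs columns {sorted(required)}")
    return [
        Gate(str(r.gate_id), r.fsc_low, r.fsc_high, r.dapi_low, r.dapi_high)
        for r in df.itertuples()
    ]


def write_partition_tsv(path, gate_counts: dict[str, int], partition: GatePartition) -> None:
    rows = [
        {"gate_id": g, "count": c, "class": "DG" if g in partition.dg_gates else "LA"}
        for g, c in sorted(gate_counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
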