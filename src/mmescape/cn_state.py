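"""Per-cell copy-number state at a target locus and pre/post state fractions.

The per-cell locus state is the modal capped copy number over the bins
overlapping the locus, with ties broken toward the lower copy number — the
conservative direction for detecting loss, which is the phenomenon of
interest at immunotherapy target loci.  States are reported on the capped
scale {0 biallelic loss, 1 monoallelic loss, 2 neutral, 3 gain, 4 ">=4"},
where raw copy numbers above four are reduced to four and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_core import (
    BinGrid,
    CellCNMatrix,
    LocusDef,
    bins_overlapping,
    CN_CAP,
)

__all__ = [
    "CellCNMatrix", "LocusStateSummary", "STATE_LABELS",
    "cap_cn", "locus_cn_state", "state_fractions", "compare_timepoints",
]

STATE_LABELS = {
    0: "biallelic loss",
    1: "monoallelic loss",
    2: "neutral",
    3: "gain",
    4: ">=4 gain",
}


def cap_cn(cn: int) -> tuple[int, bool]:
    """Cap a copy number at four; the flag marks values reported as ">=4"."""
    cn = int(cn)
    if cn < 0:
        raise ValueError(f"copy number must be >= 0, got {cn}")
    return min(cn, CN_CAP), cn > CN_CAP


def locus_cn_state(
    cell_row: np.ndarray,
    locus: LocusDef,
    grid: BinGrid,
    method: str = "mode",
) -> int:
    """Copy-number state of one cell at a locus.

    ``method="mode"`` (default) takes the modal capped CN across the locus
    bins, ties toward lower CN; ``method="median"`` takes the lower median.
    """
    bin_ids = bins_overlapping(locus, grid)
    values = np.minimum(np.asarray(cell_row)[bin_ids], CN_CAP)
    if method == "mode":
        counts = np.bincount(values, minlength=CN_CAP + 1)
        return int(np.argmax(counts))  # argmax returns the lowest of ties
    if method == "median":
        return int(np.sort(values)[(len(values) - 1) // 2])
    raise ValueError(f"unknown aggregation method {method!r}")


@dataclass
class LocusStateSummary:
    """Per-state cell counts and percentages at one locus and timepoint."""

    locus: LocusDef
    timepoint: str
    counts: dict[int, int]
    denominator: int
    percentages: dict[int, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if sum(self.counts.values()) != self.denominator:
            raise ValueError("state counts do not sum to the denominator")
        self.percentages = {
            s: 100.0 * c / self.denominator for s, c in self.counts.items()
        }

    def pct(self, state: int) -> float:
        return self.percentages.get(state, 0.0)

    def to_records(self) -> list[dict]:
        return [
            {
                "gene": self.locus.gene,
                "timepoint": self.timepoint,
                "state": s,
                "label": STATE_LABELS[s],
                "n_cells": self.counts.get(s, 0),
                "pct": self.pct(s),
            }
            for s in sorted(STATE_LABELS)
        ]


def state_fractions(
    matrix: CellCNMatrix,
    locus: LocusDef,
    timepoint: str,
    method: str = "mode",
) -> LocusStateSummary:
    """Per-state percentages over all cells of the matrix.

    The denominator is every cell in the input matrix; no tumor/normal
    discrimination is attempted (input matrices are assumed tumor-sorted).
    """
    if matrix.n_cells == 0:
        raise ValueError("empty CN matrix")
    bin_ids = bins_overlapping(locus, matrix.grid)
    sub = np.minimum(matrix.cn[:, bin_ids], CN_CAP)
    counts: dict[int, int] = {}
    for row in sub:
        bc = np.bincount(row, minlength=CN_CAP + 1)
        if method == "mode":
            s = int(np.argmax(bc))
        else:
            s = int(np.sort(row)[(len(row) - 1) // 2])
        counts[s] = counts.get(s, 0) + 1
    return LocusStateSummary(locus, timepoint, counts, matrix.n_cells)


def compare_timepoints(
    pre: LocusStateSummary, post: LocusStateSummary
) -> pd.DataFrame:
    """Delta table (state, pre %, post %, difference); missing states are 0%."""
    if pre.locus != post.locus:
        raise ValueError(
            f"locus mismatch: {pre.locus.gene} vs {post.locus.gene}"
        )
    rows = []
    for s in sorted(STATE_LABELS):
        p0, p1 = pre.pct(s), post.pct(s)
        rows.append({
            "state": s,
            "label": STATE_LABELS[s],
            "pre_pct": p0,
            "post_pct": p1,
            "delta_pct": p1 - p0,
        })
    return pd.DataFrame(rows)
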