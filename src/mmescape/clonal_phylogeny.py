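"""Clone decomposition from per-cell CN profiles and event-parsimony trees.

Cells are grouped by agglomerative clustering (average linkage) on the mean
per-bin Manhattan distance between capped CN vectors; clusters below a
minimum size are merged into their nearest cluster.  Each clone gets a
consensus profile (per-bin mode, ties toward lower CN), and the tree over
{diploid root} ∪ clones minimizes the total number of copy-number events,
where an event is a maximal run of consecutive bins (within one chromosome)
whose child-minus-parent difference is a constant nonzero delta.

All tie-breaks are deterministic (smallest cell index, smallest clone id),
so shuffling cell order changes no output.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .genomic_core import BinGrid, CellCNMatrix, GenomicInterval, CN_CAP

ROOT_ID = "root"          # implicit all-diploid root
DISTANCE_THRESHOLD = 0.15  # CN units per bin (mean Manhattan); default cut


@dataclass
class CloneAssignment:
    """cell id -> clone id, with per-clone counts and fractions."""

    mapping: dict[str, str]
    clone_ids: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.clone_ids}
        for c in self.mapping.values():
            out[c] += 1
        return out

    @property
    def fractions(self) -> dict[str, float]:
        n = len(self.mapping)
        return {c: k / n for c, k in self.counts.items()}

    def members(self, clone_id: str) -> list[str]:
        return [cell for cell, c in self.mapping.items() if c == clone_id]


@dataclass(frozen=True)
class CloneProfile:
    """Per-bin consensus integer CN (capped) of one clone."""

    clone_id: str
    grid: BinGrid
    cn: tuple[int, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.cn, dtype=np.int64)


@dataclass(frozen=True)
class CNEvent:
    """One maximal contiguous constant-delta run between parent and child."""

    interval: GenomicInterval
    bin_start: int
    bin_end: int     # inclusive
    delta: int

    def label(self) -> str:
        sign = "+" if self.delta > 0 else ""
        return f"{self.interval} {sign}{self.delta}"


@dataclass
class PhyloTree:
    """Event-parsimony tree over clones plus the implicit diploid root."""

    clone_ids: tuple[str, ...]
    parent: dict[str, str]                       # clone -> parent (or ROOT_ID)
    edge_events: dict[str, tuple[CNEvent, ...]]  # clone -> events on its edge

    @property
    def total_events(self) -> int:
        return sum(len(v) for v in self.edge_events.values())

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def to_newick(self) -> str:
        def render(node: str) -> str:
            kids = self.children(node)
            if not kids:
                return node
            return "(" + ",".join(render(k) for k in kids) + ")" + node

        return render(ROOT_ID) + ";"


def cluster_cells(
    matrix: CellCNMatrix,
    min_clone_size: int | None = None,
    distance_threshold: float = DISTANCE_THRESHOLD,
) -> CloneAssignment:
    """Group cells into clones by their capped CN profiles.

    Average-linkage agglomerative clustering on mean-per-bin Manhattan
    distance, cut at ``distance_threshold``; clusters smaller than
    ``min_clone_size`` (default ``max(3, 0.5% of cells)``) are merged into the
    nearest surviving cluster.  Clones are labeled C1, C2, ... in order of
    their smallest member cell index.
    """
    n = matrix.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if min_clone_size is None:
        min_clone_size = max(3, int(round(0.005 * n)))

    X = matrix.capped.astype(float)
    d = pdist(X, metric="cityblock") / matrix.grid.n_bins
    if np.all(d == 0):
        labels = np.ones(n, dtype=int)
    else:
        Z = linkage(d, method="average")
        labels = fcluster(Z, t=distance_threshold, criterion="distance")

    # merge undersized clusters into the nearest (by centroid distance) big one
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        small = [i for i, k in zip(ids, counts) if k < min_clone_size]
        big = [i for i, k in zip(ids, counts) if k >= min_clone_size]
        if not small or not big:
            break
        centroids = {i: X[labels == i].mean(axis=0) for i in ids}
        i = small[0]
        nearest = min(
            big,
            key=lambda j: (np.abs(centroids[i] - centroids[j]).mean(), j),
        )
        labels[labels == i] = nearest

    # deterministic relabeling by smallest member cell index
    first_index = {}
    for idx, lab in enumerate(labels):
        first_index.setdefault(lab, idx)
    order = sorted(first_index, key=first_index.get)
    rename = {lab: f"C{k + 1}" for k, lab in enumerate(order)}
    mapping = {matrix.cell_ids[i]: rename[labels[i]] for i in range(n)}
    return CloneAssignment(mapping, tuple(rename[lab] for lab in order))


def consensus_profile(
    matrix: CellCNMatrix, assignment: CloneAssignment, clone_id: str
) -> CloneProfile:
    """Per-bin modal capped CN across the clone's cells, ties toward lower CN."""
    members = [i for i, cid in enumerate(matrix.cell_ids)
               if assignment.mapping[cid] == clone_id]
    if not members:
        raise ValueError(f"clone {clone_id!r} has no member cells")
    sub = matrix.capped[members]
    prof = np.empty(matrix.grid.n_bins, dtype=np.int64)
    for b in range(matrix.grid.n_bins):
        prof[b] = np.argmax(np.bincount(sub[:, b], minlength=CN_CAP + 1))
    return CloneProfile(clone_id, matrix.grid, tuple(int(v) for v in prof))


def event_segments(parent: CloneProfile, child: CloneProfile) -> list[CNEvent]:
    """Maximal constant-delta runs of consecutive bins, per chromosome."""
    if parent.grid != child.grid:
        raise ValueError("profiles are on different bin grids")
    grid = parent.grid
    diff = child.as_array() - parent.as_array()
    events: list[CNEvent] = []
    for chrom in grid.chroms:
        bin_ids = grid.chrom_bin_ids(chrom)
        run_start = None
        run_delta = 0
        for j, b in enumerate(bin_ids + [None]):
            delta = int(diff[b]) if b is not None else 0
            if run_start is not None and (b is None or delta != run_delta):
                b0, b1 = bin_ids[run_start], bin_ids[j - 1]
                events.append(CNEvent(
                    GenomicInterval(chrom, grid.bins[b0].start, grid.bins[b1].end),
                    b0, b1, run_delta,
                ))
                run_start = None
            if b is not None and delta != 0 and run_start is None:
                run_start = j
                run_delta = delta
    return events


def _root_profile(grid: BinGrid) -> CloneProfile:
    return CloneProfile(ROOT_ID, grid, tuple([2] * grid.n_bins))


def infer_tree(profiles: Sequence[CloneProfile]) -> PhyloTree:
    """Minimum-event tree over {diploid root} ∪ clones.

    Edge cost is the number of event segments between parent and child.  For
    up to 6 clones every acyclic parent assignment is scored exhaustively;
    beyond that, clones are attached greedily (nearest already-attached
    ancestor, by event count from the root in ascending order).  Ties prefer
    the parent appearing earlier in {root, clones...} order.
    """
    if not profiles:
        raise ValueError("need at least one clone profile")
    grid = profiles[0].grid
    nodes = [_root_profile(grid)] + list(profiles)
    k = len(profiles)
    cost = np.zeros((k + 1, k + 1), dtype=int)
    segs: dict[tuple[int, int], tuple[CNEvent, ...]] = {}
    for i in range(k + 1):
        for j in range(k + 1):
            if i == j:
                continue
            ev = tuple(event_segments(nodes[i], nodes[j]))
            segs[(i, j)] = ev
            cost[i, j] = len(ev)

    if k <= 6:
        # score every parent assignment (vectorized); keep acyclic ones only
        choices = [[p for p in range(k + 1) if p != c] for c in range(1, k + 1)]
        vecs = np.array(list(itertools.product(*choices)), dtype=np.int64)
        cur = vecs.copy()
        for _ in range(k):  # k pointer-chasing steps reach the root iff acyclic
            nz = cur > 0
            rows, cols = np.nonzero(nz)
            cur[rows, cols] = vecs[rows, cur[rows, cols] - 1]
        acyclic = ~cur.any(axis=1)
        vecs = vecs[acyclic]
        totals = cost[vecs, np.arange(1, k + 1)[None, :]].sum(axis=1)
        best = totals.min()
        tied = vecs[totals == best]
        # deterministic tie-break: lexicographically smallest parent vector
        best_vec = tied[np.lexsort(tied.T[::-1])[0]]
        parent_idx = {c: int(best_vec[c - 1]) for c in range(1, k + 1)}
    else:
        order = sorted(range(1, k + 1), key=lambda c: (cost[0, c], c))
        attached = [0]
        parent_idx = {}
        for c in order:
            p = min(attached, key=lambda a: (cost[a, c], a))
            parent_idx[c] = p
            attached.append(c)

    names = [ROOT_ID] + [p.clone_id for p in profiles]
    parent = {names[c]: names[p] for c, p in parent_idx.items()}
    edge_events = {names[c]: segs[(p, c)] for c, p in parent_idx.items()}
    return PhyloTree(tuple(p.clone_id for p in profiles), parent, edge_events)


@dataclass
class FishPlotTable:
    """Per-timepoint clone fractions with parentage, fish-plot ready."""

    records: list[dict]    # timepoint, clone_id, parent, fraction_pct, events

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write(self, path: str | Path, fmt: str = "tsv") -> None:
        if fmt == "tsv":
            self.to_frame().to_csv(path, sep="\t", index=False)
        else:
            with open(path, "w") as fh:
                json.dump(self.records, fh, indent=2)
                fh.write("\n")


def fishplot_table(
    tree: PhyloTree,
    assignments: Mapping[str, CloneAssignment | Mapping[str, float]],
    tol_pct: float = 0.5,
) -> FishPlotTable:
    """Emit per-timepoint clone fractions with parentage and event labels.

    ``assignments`` maps timepoint -> CloneAssignment (or a plain clone ->
    fraction mapping).  Clones absent at a timepoint get fraction 0.  The
    per-timepoint fractions must sum to 100% within ``tol_pct``.
    """
    records = []
    for tp in assignments:
        a = assignments[tp]
        fr = a.fractions if isinstance(a, CloneAssignment) else dict(a)
        total = 100.0 * sum(fr.values())
        if abs(total - 100.0) > tol_pct:
            raise ValueError(
                f"timepoint {tp!r}: clone fractions sum to {total:.2f}%, not 100%"
            )
        for clone in tree.clone_ids:
            records.append({
                "timepoint": tp,
                "clone_id": clone,
                "parent": tree.parent[clone],
                "fraction_pct": 100.0 * fr.get(clone, 0.0),
                "events": "; ".join(e.label() for e in tree.edge_events[clone]),
            })
    for rec in records:
        if rec["fraction_pct"] < 0:
            raise ValueError("negative clone fraction")
    return FishPlotTable(records)


def write_assignment(assignment: CloneAssignment, path: str | Path) -> None:
    pd.DataFrame(
        [{"cell_id": cell, "clone_id": clone}
         for cell, clone in assignment.mapping.items()]
    ).to_csv(path, sep="\t", index=False)


def write_profiles(profiles: Sequence[CloneProfile], path: str | Path) -> None:
    grid = profiles[0].grid
    cols = {f"{b.chrom}:{b.start}-{b.end}": [p.cn[i] for p in profiles]
            for i, b in enumerate(grid.bins)}
    df = pd.DataFrame({"clone_id": [p.clone_id for p in profiles], **cols})
    df.to_csv(path, sep="\t", index=False)


def write_tree(tree: PhyloTree, newick_path: str | Path, events_path: str | Path) -> None:
    Path(newick_path).write_text(tree.to_newick() + "\n")
    payload = {
        clone: [e.label() for e in evs]
        for clone, evs in tree.edge_events.items()
    }
    with open(events_path, "w") as fh:
        json.dump({"parent": tree.parent, "edge_events": payload}, fh, indent=2)
        fh.write("\n")
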