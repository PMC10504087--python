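"""Independent brute-force oracles used by the test suite."""

import itertools

import numpy as np


def n_segments_scan(a, b, grid):
    """Count maximal constant nonzero-delta runs by a plain per-chromosome
    scan (independent of the package's event extraction)."""
    count = 0
    for chrom in grid.chroms:
        prev = 0
        for i in grid.chrom_bin_ids(chrom):
            d = int(b[i]) - int(a[i])
            if d != 0 and d != prev:
                count += 1
            prev = d
    return count


def exhaustive_min_event_tree(profiles, grid):
    """Minimum total event count over all rooted trees on {root} + clones,
    found by enumerating every acyclic parent vector."""
    nodes = [np.full(grid.n_bins, 2)] + [p.as_array() for p in profiles]
    k = len(profiles)
    pair_cost = {
        (i, j): n_segments_scan(nodes[i], nodes[j], grid)
        for i in range(k + 1) for j in range(1, k + 1) if i != j
    }
    best = None
    for vec in itertools.product(range(k + 1), repeat=k):
        if any(vec[c - 1] == c for c in range(1, k + 1)):
            continue
        ok = True
        for c in range(1, k + 1):
            node, steps = c, 0
            while node != 0 and steps <= k:
                node = vec[node - 1]
                steps += 1
            if node != 0:
                ok = False
                break
        if not ok:
            continue
        total = sum(pair_cost[(vec[c - 1], c)] for c in range(1, k + 1))
        if best is None or total < best:
            best = total
    return best
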