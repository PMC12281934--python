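"""Independent oracles used by the test suite.

Each oracle is deliberately implemented by a different route than the
library code it checks: exhaustive path enumeration for alignment scores,
plain sort-and-interpolate for percentiles, ancestor-set intersection for
MRCA queries.
"""

from __future__ import annotations

import math


def brute_force_best_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Maximum global alignment score by exhaustive enumeration.

    Walks every monotone path through the alignment grid (every distinct
    global alignment), scoring maximal gap runs as open + (k-1)*extend.
    Exponential in sequence length; intended for lengths <= ~8.
    """
    la, lb = len(a), len(b)
    best = -math.inf

    def rec(i: int, j: int, state: int, score: float) -> None:
        nonlocal best
        if i == la and j == lb:
            if score > best:
                best = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, 0, score + (match if a[i] == b[j] else mismatch))
        if i < la:
            rec(i + 1, j, 1, score + (gap_extend if state == 1 else gap_open))
        if j < lb:
            rec(i, j + 1, 2, score + (gap_extend if state == 2 else gap_open))

    rec(0, 0, 0, 0.0)
    return best


def sort_interpolate_percentile(values, p: float) -> float:
    """Quantile by hand: sort, locate h = (n-1)p, linear interpolation."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        raise ValueError("no values")
    h = (n - 1) * p
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return xs[lo]
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def mrca_by_ancestor_sets(tree, label_a: str, label_b: str):
    """MRCA by intersecting explicit ancestor lists (dendropy tree)."""
    def path_to_root(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    pa = path_to_root(leaves[label_a])
    pb = set(id(n) for n in path_to_root(leaves[label_b]))
    for node in pa:
        if id(node) in pb:
            return node
    raise AssertionError("no common ancestor in a rooted tree")


def hamming_identity_pct(a: str, b: str) -> float:
    """Percent identity of two equal-length ungapped sequences."""
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
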