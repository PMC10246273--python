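"""Split-based tree comparison and the reconstruction-potential floor.

Trees are compared as unrooted topologies through their non-trivial
bipartitions (splits): the normalized Robinson–Foulds distance is the
fraction of splits unique to either tree, while the Nye similarity softly
matches splits between the trees with a Jaccard-style score under an optimal
one-to-one alignment, rewarding near-misses that RF counts as total errors.

The *reconstruction potential* of a simulated dataset is the fraction of
true-tree edges across which the barcode did not change; those edges are
invisible to any barcode-only method, so the value is the floor on the
normalized RF such a method can achieve.
"""

from __future__ import annotations

from scipy.optimize import linear_sum_assignment

import numpy as np

from .lineage_data import LineageTree

Split = frozenset  # frozenset({frozenset(side_a), frozenset(side_b)})


def splits(tree: LineageTree) -> set[Split]:
    """Non-trivial bipartitions of the leaf set, treating the tree as
    unrooted.

    Each internal edge contributes the split {leaves below} | {rest};
    pendant edges (and the mirrored root edges) are trivial and excluded.
    """
    all_leaves = frozenset(tree.leaf_names())
    out: set[Split] = set()
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children)
            )
        if node.parent is None:
            continue
        side = below[id(node)]
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset({side, other}))
    return out


def _check_leaf_sets(t1: LineageTree, t2: LineageTree) -> None:
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)[:5]}, "
            f"only in second {sorted(l2 - l1)[:5]}"
        )


def rf_distance(t1: LineageTree, t2: LineageTree) -> float:
    """Normalized Robinson–Foulds distance in [0, 1].

    The number of splits present in exactly one tree, divided by the total
    number of non-trivial splits of both trees; 0 for identical topologies,
    1 when no split is shared.
    """
    _check_leaf_sets(t1, t2)
    s1, s2 = splits(t1), splits(t2)
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return len(s1 ^ s2) / denom


def split_score(s_i: Split, s_j: Split) -> float:
    """Jaccard-style similarity of two splits of the same leaf set.

    For sides (A1, B1) and (A2, B2), with a(X, Y) = |X∩Y| / |X∪Y|, the
    score is max(min(a(A1,A2), a(B1,B2)), min(a(A1,B2), a(B1,A2))) — the
    better of the two ways to pair up the sides, so it is symmetric and
    orientation-invariant, and equals 1 iff the splits coincide.
    """
    a1, b1 = tuple(s_i)
    a2, b2 = tuple(s_j)

    def jac(x: frozenset, y: frozenset) -> float:
        return len(x & y) / len(x | y)

    return max(min(jac(a1, a2), jac(b1, b2)), min(jac(a1, b2), jac(b1, a2)))


def nye_similarity(t1: LineageTree, t2: LineageTree) -> float:
    """Nye topological similarity in [0, 1].

    Solves the maximum-weight one-to-one alignment between the two split
    sets under :func:`split_score` and normalizes by the larger split
    count, so only identical topologies reach 1.
    """
    _check_leaf_sets(t1, t2)
    s1, s2 = sorted(splits(t1), key=sorted_key), sorted(splits(t2), key=sorted_key)
    if not s1 and not s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    score = np.zeros((len(s1), len(s2)))
    for i, si in enumerate(s1):
        for j, sj in enumerate(s2):
            score[i, j] = split_score(si, sj)
    rows, cols = linear_sum_assignment(score, maximize=True)
    return float(score[rows, cols].sum()) / max(len(s1), len(s2))


def sorted_key(split: Split):
    return sorted(sorted(side) for side in split)


def reconstruction_potential(true_tree: LineageTree) -> float:
    """Fraction of edges with identical parent and child barcodes.

    Requires a simulated truth tree annotated with a barcode on every node.
    An edge without any barcode change cannot be recovered from barcodes,
    so this value is the RF floor for barcode-only reconstruction.
    """
    edges = true_tree.edges()
    if not edges:
        raise ValueError("tree has no edges")
    unmutated = 0
    for parent, child in edges:
        if parent.barcode is None or child.barcode is None:
            missing = parent.name if parent.barcode is None else child.name
            raise ValueError(f"node {missing!r} lacks a barcode annotation")
        if tuple(parent.barcode) == tuple(child.barcode):
            unmutated += 1
    return unmutated / len(edges)
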