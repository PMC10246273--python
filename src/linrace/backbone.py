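"""Lineage backbone reconstruction from barcodes.

Cells frequently share an identical barcode (editing is slow relative to
division, and excision dropout erases distinguishing sites), so running
neighbor joining directly on all cells would resolve identical rows in an
arbitrary order.  Instead the cells are first collapsed to their ``K``
distinct barcodes; neighbor joining over those, under a pairwise-complete
Hamming distance, yields the *backbone* tree whose leaves each stand for a
group of identically barcoded cells.

Rooting: NJ produces an unrooted tree, but a lineage has a natural root —
the founding cell carried an unedited (all-``"0"``) barcode.  We therefore
add a pseudo-taxon with the unedited barcode, run NJ on ``K+1`` taxa, root
on the pseudo-taxon's edge and delete it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .lineage_data import DROPOUT, UNMUTATED, CharacterMatrix, LineageTree, Node

ROOT_PSEUDOTAXON = "__unedited_root__"


@dataclass
class UniqueBarcodeTable:
    """The ``K`` distinct barcodes of a dataset and the cells carrying each.

    Barcodes are indexed in first-occurrence order; groups partition the
    cells.
    """

    barcodes: list[tuple[str, ...]]
    groups: list[list[str]]  # groups[i] = cell ids sharing barcodes[i]

    @property
    def k(self) -> int:
        return len(self.barcodes)

    def label(self, i: int) -> str:
        return f"U{i}"

    def group_of(self, label: str) -> list[str]:
        return self.groups[int(label[1:])]


def collapse_unique(cm: CharacterMatrix) -> UniqueBarcodeTable:
    """Collapse cells to distinct barcode vectors, first-occurrence ordered."""
    seen: dict[tuple[str, ...], int] = {}
    barcodes: list[tuple[str, ...]] = []
    groups: list[list[str]] = []
    for cell, row in zip(cm.cell_ids, cm.entries):
        key = tuple(row)
        if key not in seen:
            seen[key] = len(barcodes)
            barcodes.append(key)
            groups.append([])
        groups[seen[key]].append(cell)
    return UniqueBarcodeTable(barcodes=barcodes, groups=groups)


def barcode_distance(a: tuple[str, ...] | list[str], b: tuple[str, ...] | list[str]) -> float:
    """Pairwise-complete Hamming distance between two barcodes.

    Sites where either entry is the dropout symbol carry no lineage signal
    and are excluded; the distance is mismatches / compared sites.  If no
    site is comparable (both barcodes heavily dropped out), fall back to a
    plain mismatch fraction over all sites with ``"-"`` treated as an
    ordinary symbol, so the distance is always defined.
    """
    if len(a) != len(b):
        raise ValueError(f"barcode length mismatch: {len(a)} vs {len(b)}")
    compared = 0
    mismatch = 0
    for x, y in zip(a, b):
        if x == DROPOUT or y == DROPOUT:
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        return sum(x != y for x, y in zip(a, b)) / len(a)
    return mismatch / compared


def _pairwise_distances(barcodes: list[tuple[str, ...]]) -> np.ndarray:
    k = len(barcodes)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = barcode_distance(barcodes[i], barcodes[j])
    return d


def neighbor_joining(d: np.ndarray, labels: list[str]):
    """Saitou–Nei neighbor joining; returns an unrooted skbio TreeNode.

    On additive distance matrices the generating topology is recovered
    exactly.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if d.shape[0] == 2:
        # two taxa: the unique unrooted tree is a single edge
        import skbio

        return skbio.TreeNode.read([f"({labels[0]},{labels[1]});"])
    dm = DistanceMatrix(d, ids=labels)
    return _skbio_nj(dm)


def _adjacency(sk_tree) -> tuple[dict[int, list[int]], dict[int, str]]:
    """Undirected adjacency of an skbio tree, with tip names."""
    nodes = list(sk_tree.traverse(include_self=True))
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, list[int]] = defaultdict(list)
    names: dict[int, str] = {}
    for n in nodes:
        i = index[id(n)]
        if n.is_tip():
            names[i] = n.name
        for c in n.children:
            j = index[id(c)]
            adj[i].append(j)
            adj[j].append(i)
    return adj, names


def root_at_outgroup(sk_tree, outgroup: str) -> LineageTree:
    """Root an unrooted tree at the neighbor of ``outgroup`` and drop it.

    For an unrooted binary tree this yields a rooted strictly bifurcating
    tree over the remaining taxa.
    """
    adj, names = _adjacency(sk_tree)
    out_id = next(i for i, nm in names.items() if nm == outgroup)
    if len(adj[out_id]) != 1:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf")
    root_id = adj[out_id][0]

    def build(i: int, parent: int) -> Node:
        node = Node(name=names.get(i))
        for j in adj[i]:
            if j == parent or j == out_id:
                continue
            node.add_child(build(j, i))
        return node

    return LineageTree(build(root_id, -1))


def build_backbone(cm: CharacterMatrix) -> tuple[LineageTree, UniqueBarcodeTable]:
    """Build the rooted NJ backbone over unique barcodes.

    Leaves are labeled ``U0..U{K-1}`` in first-occurrence order of the
    barcodes; each expands downstream to the group of cells sharing that
    barcode.  ``K == 1`` yields a single-leaf tree (the whole dataset is one
    group and goes straight to likelihood search).
    """
    table = collapse_unique(cm)
    if table.k == 1:
        return LineageTree(Node(name=table.label(0))), table
    labels = [table.label(i) for i in range(table.k)]
    unedited = tuple([UNMUTATED] * cm.n_targets)
    barcodes = table.barcodes + [unedited]
    d = _pairwise_distances(barcodes)
    sk_tree = neighbor_joining(d, labels + [ROOT_PSEUDOTAXON])
    tree = root_at_outgroup(sk_tree, ROOT_PSEUDOTAXON)
    return tree, table


def full_nj_tree(cm: CharacterMatrix) -> LineageTree:
    """Plain Hamming NJ over all N cells (the barcode-only baseline).

    Uses the same pairwise-complete distance and unedited-outgroup rooting
    as the backbone, but without collapsing identical barcodes, so identical
    cells are resolved in an arbitrary (NJ tie-break) order.
    """
    barcodes = cm.barcodes()
    unedited = tuple([UNMUTATED] * cm.n_targets)
    d = _pairwise_distances(barcodes + [unedited])
    sk_tree = neighbor_joining(d, list(cm.cell_ids) + [ROOT_PSEUDOTAXON])
    return root_at_outgroup(sk_tree, ROOT_PSEUDOTAXON)
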