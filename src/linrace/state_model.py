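"""Cell states, the cell state tree, and ancestral state inference.

Discrete cell states are obtained by k-means on a PCA embedding of the
expression data; their differentiation order is captured by a rooted, directed
*cell state tree* in which edges point from earlier to later states and
transitions are irreversible.  Given states at the leaves of a candidate
lineage tree, ancestral states follow the asymmetric-division rule: a parent
whose daughters share a state keeps that state, otherwise it takes the most
recent common ancestor of the two daughter states on the state tree (for two
states on one differentiation path, that is simply the earlier of the two).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .lineage_data import ExpressionMatrix, LineageTree, Node, parse_newick

logger = logging.getLogger(__name__)

INF = float("inf")


# ---------------------------------------------------------------------------
# Cell state tree
# ---------------------------------------------------------------------------


@dataclass
class CellStateTree:
    """Rooted directed tree over discrete state labels.

    Between any two states there is at most one directed path; there are no
    edges back toward the root, so differentiation is irreversible.
    """

    root: str
    parent: dict[str, str | None] = field(default_factory=dict)
    children: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, root: str, edges: list[tuple[str, str]]) -> "CellStateTree":
        parent: dict[str, str | None] = {root: None}
        children: dict[str, list[str]] = {root: []}
        for u, v in edges:
            if v in parent:
                raise ValueError(f"state {v!r} has more than one parent")
            parent.setdefault(u, None)
            children.setdefault(u, [])
            parent[v] = u
            children.setdefault(v, [])
            children[u].append(v)
        tree = cls(root=root, parent=parent, children=children)
        # reachability check: all states must descend from the root
        for s in parent:
            tree.depth(s)
        return tree

    def states(self) -> list[str]:
        return list(self.parent)

    def __contains__(self, state: str) -> bool:
        return state in self.parent

    def _require(self, state: str) -> None:
        if state not in self.parent:
            raise KeyError(f"unknown state {state!r}")

    def depth(self, state: str) -> int:
        self._require(state)
        d = 0
        s: str | None = state
        while self.parent[s] is not None:
            s = self.parent[s]
            d += 1
            if d > len(self.parent):
                raise ValueError("cycle detected in state tree")
        if s != self.root:
            raise ValueError(f"state {state!r} not reachable from root")
        return d

    def path_from_root(self, state: str) -> list[str]:
        self._require(state)
        path = [state]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def is_descendant_or_equal(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.path_from_root(descendant)

    def mrca(self, a: str, b: str) -> str:
        pa = self.path_from_root(a)
        pb = set(self.path_from_root(b))
        for s in reversed(pa):
            if s in pb:
                return s
        raise ValueError("states share no ancestor (malformed tree)")

    def geodesic(self, s_from: str, s_to: str) -> float:
        """Directed edge count from ``s_from`` down to ``s_to``; +inf if
        ``s_to`` is not a descendant-or-equal of ``s_from``."""
        self._require(s_from)
        self._require(s_to)
        if not self.is_descendant_or_equal(s_from, s_to):
            return INF
        return self.depth(s_to) - self.depth(s_from)

    def is_terminal(self, state: str) -> bool:
        self._require(state)
        return not self.children[state]

    def descendant_leaf_paths(self, state: str) -> list[list[str]]:
        """All root-ward-excluded paths from ``state`` to the leaves below it."""
        if self.is_terminal(state):
            return [[state]]
        paths = []
        for c in self.children[state]:
            for tail in self.descendant_leaf_paths(c):
                paths.append([state] + tail)
        return paths

    # -- Newick round trip ---------------------------------------------------

    def to_newick(self) -> str:
        def render(state: str) -> str:
            kids = self.children[state]
            if not kids:
                return state
            return "(" + ",".join(render(c) for c in kids) + ")" + state

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "CellStateTree":
        lt = parse_newick(text)
        edges: list[tuple[str, str]] = []

        def walk(node: Node) -> None:
            for c in node.children:
                if node.name is None or c.name is None:
                    raise ValueError("state tree Newick must label every node")
                edges.append((node.name, c.name))
                walk(c)

        walk(lt.root)
        if lt.root.name is None:
            raise ValueError("state tree Newick must label the root")
        return cls.from_edges(lt.root.name, edges)


def read_state_tree(path: str) -> CellStateTree:
    with open(path) as fh:
        return CellStateTree.from_newick(fh.read())


def write_state_tree(st: CellStateTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(st.to_newick() + "\n")


def state_geodesic(st: CellStateTree, s_from: str, s_to: str) -> float:
    return st.geodesic(s_from, s_to)


# ---------------------------------------------------------------------------
# Expression embedding and clustering
# ---------------------------------------------------------------------------


@dataclass
class ExpressionEmbedding:
    """Per-cell coordinates in a reduced expression space."""

    cell_ids: list[str]
    coords: np.ndarray  # (N, n_pcs)
    meta: dict = field(default_factory=dict)

    def row(self, cell_id: str) -> np.ndarray:
        return self.coords[self.cell_ids.index(cell_id)]


TARGET_LIBRARY_SIZE = 1e4


def preprocess_expression(
    em: ExpressionMatrix, n_hvg: int = 100, n_pcs: int = 20, seed: int = 0
) -> ExpressionEmbedding:
    """Normalize, log-transform, select HVGs and project to principal
    components.

    Counts are scaled to a common library size, log1p-transformed, the
    ``n_hvg`` genes with the highest log-scale variance are kept, and the
    result is projected onto the first ``n_pcs`` PCs (full SVD, so the
    embedding is deterministic).
    """
    counts = em.counts
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    logx = np.log1p(counts / lib * TARGET_LIBRARY_SIZE)
    var = logx.var(axis=0)
    if n_hvg < logx.shape[1]:
        hvg = np.sort(np.argsort(var, kind="stable")[::-1][:n_hvg])
    else:
        if n_hvg > logx.shape[1]:
            logger.warning(
                "requested %d HVGs but only %d genes present; using all",
                n_hvg,
                logx.shape[1],
            )
        hvg = np.arange(logx.shape[1])
    sub = logx[:, hvg]
    n_pcs_eff = min(n_pcs, sub.shape[1], sub.shape[0])
    if n_pcs_eff < n_pcs:
        logger.warning("reducing n_pcs from %d to %d", n_pcs, n_pcs_eff)
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(sub)
    return ExpressionEmbedding(
        cell_ids=list(em.cell_ids),
        coords=coords,
        meta={"n_hvg": int(len(hvg)), "n_pcs": int(n_pcs_eff), "normalization": "library-size+log1p"},
    )


def infer_cell_states(emb: ExpressionEmbedding, k: int = 7, seed: int = 0) -> dict[str, str]:
    """Partition cells into ``k`` states by k-means on the embedding.

    States are labeled ``S1..Sk`` in order of first appearance along the cell
    list, so identical inputs always give identical labelings.
    """
    n = len(emb.cell_ids)
    if k < 1:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(emb.coords)
    relabel: dict[int, str] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = f"S{len(relabel) + 1}"
    return {cell: relabel[lab] for cell, lab in zip(emb.cell_ids, raw)}


def state_centroids(
    emb: ExpressionEmbedding, states: dict[str, str]
) -> tuple[list[str], np.ndarray]:
    labels = sorted(set(states.values()))
    cents = np.zeros((len(labels), emb.coords.shape[1]))
    for i, lab in enumerate(labels):
        rows = [j for j, c in enumerate(emb.cell_ids) if states[c] == lab]
        cents[i] = emb.coords[rows].mean(axis=0)
    return labels, cents


def infer_state_tree(
    emb: ExpressionEmbedding, states: dict[str, str], root_state: str
) -> CellStateTree:
    """Infer the cell state tree as the centroid-distance MST rooted at
    ``root_state``.

    The minimum spanning tree over Euclidean distances between state
    centroids in the embedding captures which states are adjacent along the
    differentiation trajectories; orienting every edge away from the chosen
    root makes the transitions directed and irreversible.
    """
    labels, cents = state_centroids(emb, states)
    if root_state not in labels:
        raise ValueError(f"root state {root_state!r} not among assigned states {labels}")
    if len(labels) == 1:
        return CellStateTree.from_edges(root_state, [])
    d = cdist(cents, cents)
    mst = minimum_spanning_tree(d).toarray()
    adj: dict[int, list[int]] = {i: [] for i in range(len(labels))}
    for i in range(len(labels)):
        for j in range(len(labels)):
            if mst[i, j] > 0 or mst[j, i] > 0:
                if j not in adj[i]:
                    adj[i].append(j)
    root_i = labels.index(root_state)
    edges: list[tuple[str, str]] = []
    stack = [root_i]
    seen = {root_i}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                edges.append((labels[u], labels[v]))
                stack.append(v)
    return CellStateTree.from_edges(root_state, edges)


# ---------------------------------------------------------------------------
# Ancestral state inference
# ---------------------------------------------------------------------------


def infer_ancestral_states(
    tree: LineageTree, leaf_states: dict[str, str], st: CellStateTree
) -> dict[int, str]:
    """Assign a state to every node of a bifurcating tree, bottom-up.

    Returns a map from ``id(node)`` to state and also writes the state onto
    each node in place.  Parent rule: same state if daughters agree, else the
    state-tree MRCA of the daughter states — equivalently, for two states on
    one differentiation path, the earlier one.
    """
    assignment: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in leaf_states:
                raise KeyError(f"no state for leaf {node.name!r}")
            node.state = leaf_states[node.name]
        else:
            if len(node.children) != 2:
                raise ValueError(
                    f"internal node {node.name!r} has {len(node.children)} "
                    "children; ancestral inference requires a binary tree"
                )
            s1, s2 = node.children[0].state, node.children[1].state
            node.state = s1 if s1 == s2 else st.mrca(s1, s2)
        assignment[id(node)] = node.state
    return assignment
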