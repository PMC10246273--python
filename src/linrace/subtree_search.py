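"""Resolving identical-barcode groups by likelihood hill climbing, and the
end-to-end reconstruction pipeline.

Cells sharing one barcode are indistinguishable from their barcodes alone;
their division order is recovered from expression instead.  For each group a
bifurcating *gene expression subtree* (GES) is found by hill climbing over
rooted binary topologies with the random subtree-swap (rSS) proposal —
exchange two non-nested subtrees, which preserves binarity and the leaf set
— accepting strictly improving moves, restarting from random topologies once
a local optimum is reached, and returning the best local optimum found
within the iteration budget.  The GESes are then grafted onto the backbone
at their barcode's leaf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

from . import backbone as _backbone
from .lineage_data import CharacterMatrix, ExpressionMatrix, LineageTree, Node
from .likelihood import (
    KernelCache,
    LikelihoodParams,
    build_kernel_cache,
    estimate_pa,
    total_loglik,
)
from .state_model import (
    CellStateTree,
    ExpressionEmbedding,
    infer_ancestral_states,
    infer_cell_states,
    infer_state_tree,
    preprocess_expression,
)

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Budgets and seeding for the per-group local search.

    The per-group proposal budget is ``min(max_iter_per_search,
    iteration_scaling(n))`` with the default scaling ``50·n``; a restart is
    triggered after ``no_improve_window(n)`` consecutive rejections
    (default ``max(50, 5·n)``).
    """

    max_iter_per_search: int = 500
    iteration_scaling: Callable[[int], int] = field(default=lambda n: 50 * n)
    no_improve_window: Callable[[int], int] = field(default=lambda n: max(50, 5 * n))
    seed: int = 0


@dataclass
class SearchTrace:
    """Diagnostics of one group's hill climb."""

    best_loglik: list[float] = field(default_factory=list)
    accepted: int = 0
    restarts: list[int] = field(default_factory=list)  # iteration index of each restart


# ---------------------------------------------------------------------------
# Tree proposals
# ---------------------------------------------------------------------------


def random_bifurcating_tree(leaf_ids: list[str], seed_or_rng) -> LineageTree:
    """Uniformly random rooted binary topology over ``leaf_ids``.

    Built by sequential random insertion: the k-th leaf attaches to one of
    the ``2k−3`` edges or above the root, each equally likely, which makes
    all ``(2n−3)!!`` rooted binary topologies equiprobable.
    """
    if not leaf_ids:
        raise ValueError("need at least one leaf")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    root = Node(name=leaf_ids[0])
    tree = LineageTree(root)
    for leaf_id in leaf_ids[1:]:
        # attachment points: above any existing node (= on its parent edge,
        # or above the root)
        nodes = tree.nodes()
        target = nodes[rng.integers(len(nodes))]
        new_internal = Node()
        new_leaf = Node(name=leaf_id)
        parent = target.parent
        if parent is None:
            tree.root = new_internal
        else:
            parent.children[parent.children.index(target)] = new_internal
            new_internal.parent = parent
        new_internal.children = []
        new_internal.add_child(target)
        new_internal.add_child(new_leaf)
    return tree


def _is_ancestor(a: Node, b: Node) -> bool:
    node = b
    while node is not None:
        if node is a:
            return True
        node = node.parent
    return False


def rss_move(tree: LineageTree, rng: np.random.Generator) -> LineageTree:
    """One random subtree swap: exchange two non-nested, non-root subtrees.

    Returns a new tree; the input is untouched.  Because the two pruned
    subtrees are regrafted at each other's positions, the result is binary
    with the same leaf set.
    """
    if tree.n_leaves < 2:
        raise ValueError("rSS requires at least 2 leaves")
    new = tree.copy()
    nonroot = [n for n in new.preorder() if n.parent is not None]
    a = nonroot[rng.integers(len(nonroot))]
    candidates = [
        n for n in nonroot if n is not a and not _is_ancestor(n, a) and not _is_ancestor(a, n)
    ]
    b = candidates[rng.integers(len(candidates))]
    pa_, pb_ = a.parent, b.parent
    ia = pa_.children.index(a)
    ib = pb_.children.index(b)
    pa_.children[ia], pb_.children[ib] = b, a
    a.parent, b.parent = pb_, pa_
    return new


def _nj_init_tree(cells: list[str], coords: np.ndarray) -> LineageTree:
    """Deterministic initial topology: NJ over within-group expression
    distances, rooted on the first cell's edge."""
    d = cdist(coords, coords)
    sk = _backbone.neighbor_joining(d, list(cells))
    # root on the first cell's pendant edge: re-root so that cell's
    # attachment node becomes the root, keeping the cell as a leaf
    adj, names = _backbone._adjacency(sk)
    first = next(i for i, nm in names.items() if nm == cells[0])
    root_id = adj[first][0]

    def build(i: int, parent: int) -> Node:
        node = Node(name=names.get(i))
        for j in adj[i]:
            if j != parent:
                node.add_child(build(j, i))
        return node

    root = Node()
    root.add_child(Node(name=cells[0]))
    inner = build(root_id, first)
    root.add_child(inner)
    return _suppress_unifurcations(LineageTree(root))


def _suppress_unifurcations(tree: LineageTree) -> LineageTree:
    changed = True
    while changed:
        changed = False
        for node in tree.nodes():
            if not node.is_leaf and len(node.children) == 1:
                child = node.children[0]
                if node.parent is None:
                    child.parent = None
                    tree.root = child
                else:
                    node.parent.children[node.parent.children.index(node)] = child
                    child.parent = node.parent
                changed = True
    return tree


# ---------------------------------------------------------------------------
# Local search
# ---------------------------------------------------------------------------


def local_search(
    group_cells: list[str],
    leaf_states: dict[str, str],
    st: CellStateTree,
    kc: KernelCache | None,
    params: LikelihoodParams,
    cfg: SearchConfig,
) -> tuple[LineageTree, SearchTrace]:
    """Find the highest-likelihood bifurcating tree over one barcode group.

    Groups of one or two cells have a unique topology.  Larger groups are
    hill-climbed: the first climb starts from an expression-NJ tree, later
    restarts from uniformly random topologies; a proposal is accepted only
    if it strictly improves the total log-likelihood.
    """
    trace = SearchTrace()
    n = len(group_cells)
    if n == 1:
        return LineageTree(Node(name=group_cells[0])), trace
    if n == 2:
        root = Node()
        root.add_child(Node(name=group_cells[0]))
        root.add_child(Node(name=group_cells[1]))
        return LineageTree(root), trace

    rng = np.random.default_rng(cfg.seed)

    def score(t: LineageTree) -> float:
        infer_ancestral_states(t, leaf_states, st)
        return total_loglik(t, st, kc, params)

    budget = min(cfg.max_iter_per_search, cfg.iteration_scaling(n))
    window = cfg.no_improve_window(n)

    if kc is not None and all(c in kc.index for c in group_cells):
        coords = np.vstack([kc.coords[kc.index[c]] for c in group_cells])
        current = _nj_init_tree(group_cells, coords)
    else:
        current = random_bifurcating_tree(group_cells, rng)
    current_ll = score(current)
    best, best_ll = current, current_ll

    rejects = 0
    iteration = 0
    while iteration < budget:
        proposal = rss_move(current, rng)
        prop_ll = score(proposal)
        iteration += 1
        if prop_ll > current_ll:
            current, current_ll = proposal, prop_ll
            trace.accepted += 1
            rejects = 0
            if current_ll > best_ll:
                best, best_ll = current, current_ll
        else:
            rejects += 1
        trace.best_loglik.append(best_ll)
        if rejects >= window and iteration < budget:
            # local optimum: restart from a fresh random topology
            trace.restarts.append(iteration)
            current = random_bifurcating_tree(group_cells, rng)
            current_ll = score(current)
            if current_ll > best_ll:
                best, best_ll = current, current_ll
            rejects = 0

    infer_ancestral_states(best, leaf_states, st)
    return best, trace


# ---------------------------------------------------------------------------
# Assembly and pipeline
# ---------------------------------------------------------------------------


def assemble_tree(
    backbone_tree: LineageTree, ges_map: dict[str, LineageTree]
) -> LineageTree:
    """Replace each backbone leaf by its group's gene expression subtree."""
    if backbone_tree.root.is_leaf:
        label = backbone_tree.root.name
        if label not in ges_map:
            raise KeyError(f"no subtree for backbone leaf {label!r}")
        return ges_map[label].copy()
    out = backbone_tree.copy()
    for leaf in out.leaves():
        if leaf.name not in ges_map:
            raise KeyError(f"no subtree for backbone leaf {leaf.name!r}")
        sub = ges_map[leaf.name].copy()
        sub.root.length = 1.0
        parent = leaf.parent
        parent.children[parent.children.index(leaf)] = sub.root
        sub.root.parent = parent
    return out


@dataclass
class PipelineOptions:
    """End-to-end reconstruction settings (defaults match routine use:
    λ1=10, λ2=1, pa=0.8, 100 HVGs, 20 PCs, 7 states, 500-iteration cap)."""

    n_hvg: int = 100
    n_pcs: int = 20
    k_states: int = 7
    root_state: str | None = None
    root_cell: str | None = None
    params: LikelihoodParams = field(default_factory=LikelihoodParams)
    search: SearchConfig = field(default_factory=SearchConfig)
    states: dict[str, str] | None = None  # user-supplied leaf states
    state_tree: CellStateTree | None = None  # user-supplied state tree
    estimate_pa: bool = False
    seed: int = 0


def run_linrace(
    cm: CharacterMatrix, em: ExpressionMatrix, options: PipelineOptions | None = None
) -> tuple[LineageTree, dict]:
    """Reconstruct the cell division tree from paired barcodes and
    expression.

    Stages: NJ backbone over unique barcodes → cell states and state tree
    (inferred from expression, or taken from ``options.states`` /
    ``options.state_tree``) → RBF kernel cache → per-group likelihood search
    → grafting onto the backbone → ancestral states on the full tree.
    Returns the stated tree and a run report.
    """
    options = options or PipelineOptions()
    report: dict = {"seed": options.seed}

    try:
        bb, table = _backbone.build_backbone(cm)
    except Exception as exc:
        raise RuntimeError(f"backbone stage failed: {exc}") from exc
    report["n_cells"] = cm.n_cells
    report["n_unique_barcodes"] = table.k
    report["group_sizes"] = [len(g) for g in table.groups]

    try:
        em_aligned = em.aligned_to(cm.cell_ids)
        emb = preprocess_expression(
            em_aligned, n_hvg=options.n_hvg, n_pcs=options.n_pcs, seed=options.seed
        )
        if options.states is not None:
            states = dict(options.states)
        else:
            states = infer_cell_states(emb, k=options.k_states, seed=options.seed)
        if options.state_tree is not None:
            st = options.state_tree
        else:
            root_state = options.root_state
            if root_state is None:
                if options.root_cell is None:
                    raise ValueError(
                        "state-tree inference needs root_state or root_cell"
                    )
                root_state = states[options.root_cell]
            st = infer_state_tree(emb, states, root_state)
        report["n_states"] = len(st.states())
    except Exception as exc:
        raise RuntimeError(f"state-model stage failed: {exc}") from exc

    params = options.params
    try:
        kc = build_kernel_cache(emb, params)
    except Exception as exc:
        raise RuntimeError(f"kernel stage failed: {exc}") from exc

    if options.estimate_pa:
        largest = max(range(table.k), key=lambda i: len(table.groups[i]))
        cells = table.groups[largest]
        if len(cells) >= 3:
            coords = np.vstack([kc.coords[kc.index[c]] for c in cells])
            init = _nj_init_tree(cells, coords)
            infer_ancestral_states(init, states, st)
            params = LikelihoodParams(
                lambda1=params.lambda1,
                lambda2=params.lambda2,
                pa=estimate_pa(init, default=params.pa),
                unreachable_penalty=params.unreachable_penalty,
                sigma=params.sigma,
            )
    report["pa"] = params.pa

    master = np.random.default_rng(options.seed)
    group_seeds = master.integers(0, 2**31 - 1, size=table.k)
    ges_map: dict[str, LineageTree] = {}
    group_logliks: list[float | None] = []
    try:
        for i in range(table.k):
            cells = table.groups[i]
            cfg = SearchConfig(
                max_iter_per_search=options.search.max_iter_per_search,
                iteration_scaling=options.search.iteration_scaling,
                no_improve_window=options.search.no_improve_window,
                seed=int(group_seeds[i]),
            )
            ges, trace = local_search(cells, states, st, kc, params, cfg)
            ges_map[table.label(i)] = ges
            group_logliks.append(trace.best_loglik[-1] if trace.best_loglik else None)
            if len(cells) >= 3:
                logger.info(
                    "group %s: %d cells, best loglik %.3f, %d accepted, %d restarts",
                    table.label(i), len(cells),
                    trace.best_loglik[-1], trace.accepted, len(trace.restarts),
                )
    except Exception as exc:
        raise RuntimeError(f"subtree-search stage failed: {exc}") from exc
    report["group_logliks"] = group_logliks

    try:
        full = assemble_tree(bb, ges_map)
        infer_ancestral_states(full, states, st)
    except Exception as exc:
        raise RuntimeError(f"assembly stage failed: {exc}") from exc
    report["backbone_newick"] = bb.to_newick()
    return full, report
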