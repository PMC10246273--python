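"""Synthetic paired lineage-barcode + expression data on a known division
tree.

The generator emulates a CRISPR lineage-recording experiment:

* a perfect binary division tree of ``n_cells = 2^d`` leaves, on which cell
  states evolve by *asymmetric division* — at each division of a
  non-terminal cell, with probability ``pa`` one daughter advances along the
  cell state tree (a random number of states down a random descendant path)
  while the other keeps the parent's state;
* CRISPR barcodes of ``M`` target sites: the founder is unedited
  (all ``"0"``); along each edge every still-unmutated site mutates with
  probability ``mu`` to an allele from a configurable outcome distribution;
  mutations never revert.  With dropout enabled, two or more new cuts on one
  edge excise the targets strictly between the outermost cuts, recorded as
  ``"-"`` — dropout is inherited and irreversible and may erase earlier
  mutations;
* expression counts: each state has a mean log-expression vector generated
  by a Gaussian random walk along the state tree, so transcriptomic
  distance grows with differentiation distance; per-cell counts are
  negative-binomial around the state mean with a lognormal library size.

Every node of the returned tree carries its true state and barcode, which
downstream evaluation (reconstruction potential, ancestral-state checks)
relies on.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .lineage_data import (
    DROPOUT,
    UNMUTATED,
    CharacterMatrix,
    ExpressionMatrix,
    LineageTree,
    Node,
    write_character_matrix,
    write_expression,
    write_newick,
    write_states,
)
from .state_model import CellStateTree, write_state_tree


@dataclass
class SimConfig:
    """Simulation settings.

    ``mu`` is the per-target per-division mutation probability (realistic
    recorders span roughly 0.05–0.4); ``pa`` the asymmetric division rate;
    ``step_size`` discretizes the macro state tree into unit transitions;
    ``advance_steps`` the support of the (uniform) number of states an
    advancing daughter traverses, modeling variable developmental speed.
    """

    n_cells: int = 256
    mu: float = 0.1
    n_targets: int = 16
    n_alleles: int = 30
    allele_bias: str = "uniform"  # or "power-law"
    dropout: bool = True
    pa: float = 0.8
    # default state tree: root plus three branches of macro length 8.5,
    # discretized at step 0.5 into 3 × 17 + 1 = 52 states — deep enough
    # that lineages rarely exhaust a differentiation path
    state_tree_shape: str = "balanced"  # or "path", "custom"
    n_macro_states: int = 4
    macro_edge_length: float = 8.5
    step_size: float = 0.5
    custom_edges: list | None = None  # [(parent, child, length), ...]
    advance_steps: tuple[int, ...] = (1, 2)
    n_genes: int = 500
    root_log_mean: float = 1.0
    root_log_sd: float = 0.5
    drift_sd: float = 0.4
    lineage_drift_sd: float = 0.3
    nb_size: float = 4.0
    lib_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (0.0 < self.pa < 1.0):
            raise ValueError("pa must lie strictly inside (0, 1)")
        d = math.log2(self.n_cells)
        if d != int(d) or self.n_cells < 2:
            raise ValueError("n_cells must be a power of two >= 2")

    @property
    def depth(self) -> int:
        return int(math.log2(self.n_cells))


@dataclass
class SimulatedDataset:
    """Ground truth plus observations for one simulated experiment."""

    true_tree: LineageTree  # states and barcodes on every node
    character_matrix: CharacterMatrix  # leaves only
    expression: ExpressionMatrix
    state_assignment: dict[str, str]  # leaves
    state_tree: CellStateTree
    config: SimConfig


# ---------------------------------------------------------------------------
# State tree
# ---------------------------------------------------------------------------


def make_state_tree(
    shape: str = "balanced",
    n_macro_states: int = 3,
    step_size: float = 0.5,
    edge_length: float = 4.0,
    custom_edges: list | None = None,
) -> CellStateTree:
    """Discretize a macro state tree into unit-step states.

    Each macro edge of length ``L`` is subdivided into ``ceil(L /
    step_size)`` discrete transitions; the intermediate states of a macro
    edge toward macro state ``X`` are named ``X.1, X.2, …`` with the last
    renamed to ``X`` itself.
    """
    if shape == "path":
        macro = [
            (f"M{i}", f"M{i + 1}", edge_length) for i in range(n_macro_states - 1)
        ]
        macro_root = "M0"
    elif shape == "balanced":
        n_branch = n_macro_states - 1
        if n_branch < 1:
            macro, macro_root = [], "M0"
        else:
            macro = [("M0", f"M{i + 1}", edge_length) for i in range(n_branch)]
            macro_root = "M0"
    elif shape == "custom":
        if not custom_edges:
            raise ValueError("custom shape requires custom_edges")
        macro = [(u, v, float(l)) for u, v, l in custom_edges]
        children = {u for u, _, _ in macro}
        kids = {v for _, v, _ in macro}
        roots = children - kids
        if len(roots) != 1:
            raise ValueError("custom edges must define exactly one root")
        macro_root = roots.pop()
    else:
        raise ValueError(f"unknown state tree shape {shape!r}")

    edges: list[tuple[str, str]] = []
    for u, v, length in macro:
        n_steps = max(1, math.ceil(length / step_size))
        prev = u
        for j in range(1, n_steps + 1):
            name = v if j == n_steps else f"{v}.{j}"
            edges.append((prev, name))
            prev = name
    return CellStateTree.from_edges(macro_root, edges)


# ---------------------------------------------------------------------------
# Division tree with states
# ---------------------------------------------------------------------------


def simulate_division_tree(cfg: SimConfig, st: CellStateTree, rng=None) -> LineageTree:
    """Perfect binary division tree with asymmetric state transitions.

    The root carries the state-tree root.  At each division of a cell whose
    state still has descendants, with probability ``pa`` one uniformly
    chosen daughter advances ``k`` states (``k`` uniform on
    ``advance_steps``, truncated at the end of a uniformly chosen descendant
    path) and the other keeps the parent state; otherwise, and always for
    terminal-state cells, both daughters keep it.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    root = Node(name="n0", state=st.root)
    counter = [1]
    leaf_counter = [0]

    def divide(node: Node, depth: int) -> None:
        if depth == cfg.depth:
            node.name = f"c{leaf_counter[0]}"
            leaf_counter[0] += 1
            return
        s = node.state
        states = [s, s]
        if not st.is_terminal(s) and rng.random() < cfg.pa:
            paths = st.descendant_leaf_paths(s)
            path = paths[rng.integers(len(paths))]
            k = int(cfg.advance_steps[rng.integers(len(cfg.advance_steps))])
            k = min(k, len(path) - 1)
            advancing = int(rng.integers(2))
            states[advancing] = path[k]
        for child_state in states:
            child = Node(name=f"n{counter[0]}", state=child_state)
            counter[0] += 1
            node.add_child(child)
        for child in node.children:
            divide(child, depth + 1)

    divide(root, 0)
    return LineageTree(root)


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------


def _allele_probs(cfg: SimConfig) -> np.ndarray:
    if cfg.allele_bias == "uniform":
        p = np.ones(cfg.n_alleles)
    elif cfg.allele_bias == "power-law":
        p = 1.0 / np.arange(1, cfg.n_alleles + 1)
    else:
        raise ValueError(f"unknown allele_bias {cfg.allele_bias!r}")
    return p / p.sum()


def simulate_barcodes(
    tree: LineageTree, cfg: SimConfig, rng=None
) -> CharacterMatrix:
    """Evolve CRISPR barcodes down the tree; annotates every node in place.

    Along each edge, every unmutated site independently mutates with
    probability ``mu``; if dropout is enabled and at least two new mutations
    occur on one edge, the sites strictly between the outermost new cuts are
    excised to ``"-"`` (the cut sites keep their new alleles).  Mutated and
    dropped sites never change again.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    probs = _allele_probs(cfg)
    alleles = [str(i) for i in range(1, cfg.n_alleles + 1)]
    tree.root.barcode = tuple([UNMUTATED] * cfg.n_targets)

    for node in tree.preorder():
        if node.parent is None:
            continue
        bc = list(node.parent.barcode)
        new_sites = [
            i
            for i in range(cfg.n_targets)
            if bc[i] == UNMUTATED and rng.random() < cfg.mu
        ]
        for i in new_sites:
            bc[i] = alleles[rng.choice(cfg.n_alleles, p=probs)]
        if cfg.dropout and len(new_sites) >= 2:
            lo, hi = min(new_sites), max(new_sites)
            for i in range(lo + 1, hi):
                bc[i] = DROPOUT
        node.barcode = tuple(bc)

    leaves = tree.leaves()
    entries = np.array([list(l.barcode) for l in leaves], dtype=object)
    return CharacterMatrix(
        cell_ids=[l.name for l in leaves],
        target_ids=[f"t{i}" for i in range(cfg.n_targets)],
        entries=entries,
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    source: "LineageTree | dict[str, str]",
    st: CellStateTree,
    cfg: SimConfig,
    rng=None,
) -> ExpressionMatrix:
    """State- and lineage-driven negative-binomial counts.

    Each cell's latent log-expression is a state component plus a heritable
    lineage component.  The state component follows a Gaussian random walk
    along the state tree (each state-tree edge adds independent
    N(0, drift_sd²) per gene), so centroids separate with differentiation
    distance.  When ``source`` is the division tree, a Brownian residual
    accumulates along it (each division adds N(0, lineage_drift_sd²) per
    gene), so close relatives — in particular siblings — are transcriptomic
    neighbors even within a state, as in a recorder experiment where
    expression programs are inherited at division.  Passing a plain
    ``{cell: state}`` map instead drops the heritable component.

    Counts are gamma–Poisson (negative binomial, dispersion ``nb_size``)
    around ``exp(latent) × library size`` with a lognormal library size.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    means: dict[str, np.ndarray] = {
        st.root: rng.normal(cfg.root_log_mean, cfg.root_log_sd, size=cfg.n_genes)
    }
    # walk the state tree root-down (parents before children)
    pending = [st.root]
    while pending:
        s = pending.pop(0)
        for c in sorted(st.children[s]):
            means[c] = means[s] + rng.normal(0.0, cfg.drift_sd, size=cfg.n_genes)
            pending.append(c)

    if isinstance(source, dict):
        leaf_states = dict(source)
        latent = {cell: means[state] for cell, state in leaf_states.items()}
    else:
        leaf_states = {}
        residual: dict[int, np.ndarray] = {}
        for node in source.preorder():
            if node.parent is None:
                residual[id(node)] = np.zeros(cfg.n_genes)
            else:
                residual[id(node)] = residual[id(node.parent)] + rng.normal(
                    0.0, cfg.lineage_drift_sd, size=cfg.n_genes
                )
        latent = {}
        for leaf in source.leaves():
            leaf_states[leaf.name] = leaf.state
            latent[leaf.name] = means[leaf.state] + residual[id(leaf)]

    cells = list(leaf_states)
    counts = np.zeros((len(cells), cfg.n_genes))
    for i, cell in enumerate(cells):
        mu_vec = np.exp(latent[cell])
        lib = rng.lognormal(0.0, cfg.lib_sigma)
        m = mu_vec * lib
        lam = rng.gamma(shape=cfg.nb_size, scale=m / cfg.nb_size)
        counts[i] = rng.poisson(lam)
    return ExpressionMatrix(
        cell_ids=cells,
        gene_ids=[f"g{j}" for j in range(cfg.n_genes)],
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate one complete dataset: truth tree, barcodes, expression,
    states and state tree, all driven by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    st = make_state_tree(
        shape=cfg.state_tree_shape,
        n_macro_states=cfg.n_macro_states,
        step_size=cfg.step_size,
        edge_length=cfg.macro_edge_length,
        custom_edges=cfg.custom_edges,
    )
    tree = simulate_division_tree(cfg, st, rng)
    cm = simulate_barcodes(tree, cfg, rng)
    leaf_states = {l.name: l.state for l in tree.leaves()}
    em = simulate_expression(tree, st, cfg, rng)
    # Emit cells in random order.  Division-tree traversal order encodes
    # true sibling adjacency, and identical-barcode cells are at zero
    # pairwise distance, so any order-sensitive consumer (e.g. NJ
    # tie-breaking) would otherwise read ground truth straight out of the
    # row order — something no real experiment provides.
    perm = rng.permutation(cfg.n_cells)
    cm = CharacterMatrix(
        cell_ids=[cm.cell_ids[i] for i in perm],
        target_ids=cm.target_ids,
        entries=cm.entries[perm],
    )
    em = ExpressionMatrix(
        cell_ids=[em.cell_ids[i] for i in perm],
        gene_ids=em.gene_ids,
        counts=em.counts[perm],
    )
    return SimulatedDataset(
        true_tree=tree,
        character_matrix=cm,
        expression=em,
        state_assignment=leaf_states,
        state_tree=st,
        config=cfg,
    )


def save_dataset(ds: SimulatedDataset, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_newick(ds.true_tree, os.path.join(outdir, "true_tree.nwk"), with_states=True)
    write_character_matrix(ds.character_matrix, os.path.join(outdir, "barcodes.tsv"))
    write_expression(ds.expression, os.path.join(outdir, "expression.csv"))
    write_states(ds.state_assignment, os.path.join(outdir, "states.tsv"))
    write_state_tree(ds.state_tree, os.path.join(outdir, "state_tree.nwk"))
    all_bc = CharacterMatrix(
        cell_ids=[n.name for n in ds.true_tree.preorder()],
        target_ids=ds.character_matrix.target_ids,
        entries=np.array(
            [list(n.barcode) for n in ds.true_tree.preorder()], dtype=object
        ),
    )
    write_character_matrix(all_bc, os.path.join(outdir, "all_barcodes.tsv"))
    cfg = asdict(ds.config)
    cfg["advance_steps"] = list(cfg["advance_steps"])
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2)
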