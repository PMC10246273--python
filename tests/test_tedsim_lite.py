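"""tedsim_lite: state tree, division tree, barcodes, expression, composition."""

import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from linrace.lineage_data import DROPOUT, UNMUTATED
from linrace.state_model import INF
from linrace.tedsim_lite import (
    SimConfig,
    make_state_tree,
    simulate_barcodes,
    simulate_dataset,
    simulate_division_tree,
    simulate_expression,
    save_dataset,
)
from linrace.tree_metrics import reconstruction_potential


# ---------------------------------------------------------------------------
# SimConfig
# ---------------------------------------------------------------------------


def test_config_requires_power_of_two():
    with pytest.raises(ValueError):
        SimConfig(n_cells=100)


def test_config_validates_rates():
    with pytest.raises(ValueError):
        SimConfig(mu=1.5)
    with pytest.raises(ValueError):
        SimConfig(pa=0.0)


def test_default_state_tree_has_52_states():
    cfg = SimConfig()
    st = make_state_tree(
        shape=cfg.state_tree_shape,
        n_macro_states=cfg.n_macro_states,
        step_size=cfg.step_size,
        edge_length=cfg.macro_edge_length,
    )
    assert len(st.states()) == 52


# ---------------------------------------------------------------------------
# make_state_tree
# ---------------------------------------------------------------------------


def test_state_tree_path_subdivision():
    st = make_state_tree(shape="path", n_macro_states=2, step_size=0.5, edge_length=2.0)
    # one macro edge of length 2 at step 0.5 -> root + 4 states in a chain
    assert len(st.states()) == 5
    assert all(len(st.children[s]) <= 1 for s in st.states())
    assert st.depth("M1") == 4


def test_state_tree_step_at_least_length_keeps_macro_states():
    st = make_state_tree(shape="path", n_macro_states=3, step_size=5.0, edge_length=2.0)
    assert sorted(st.states()) == ["M0", "M1", "M2"]


def test_state_tree_balanced_two_branches():
    st = make_state_tree(
        shape="balanced", n_macro_states=3, step_size=1.0, edge_length=3.0
    )
    root = st.root
    assert len(st.children[root]) == 2
    # two root-disjoint chains below the root
    for c in st.children[root]:
        path = [c]
        while st.children[path[-1]]:
            assert len(st.children[path[-1]]) == 1
            path.append(st.children[path[-1]][0])
        assert len(path) == 3


# ---------------------------------------------------------------------------
# simulate_division_tree
# ---------------------------------------------------------------------------


def test_division_tree_shape_and_root_state():
    cfg = SimConfig(n_cells=64, seed=0)
    st = make_state_tree(
        shape=cfg.state_tree_shape,
        n_macro_states=cfg.n_macro_states,
        step_size=cfg.step_size,
        edge_length=cfg.macro_edge_length,
    )
    tree = simulate_division_tree(cfg, st, np.random.default_rng(0))
    assert tree.n_leaves == 64
    assert tree.is_bifurcating()
    assert tree.root.state == st.root


def test_division_tree_pa_near_zero_keeps_root_state():
    cfg = SimConfig(n_cells=32, pa=1e-12, seed=1)
    st = make_state_tree(shape="path", n_macro_states=4, step_size=1.0, edge_length=3.0)
    tree = simulate_division_tree(cfg, st, np.random.default_rng(1))
    assert all(leaf.state == st.root for leaf in tree.leaves())


def test_division_tree_single_step_advances():
    # chain state tree, pa ~ 1, one state per transition: every edge geodesic
    # is 0 or 1 and exactly one child advances at each eligible division
    cfg = SimConfig(n_cells=64, pa=1 - 1e-12, advance_steps=(1,), seed=2)
    st = make_state_tree(shape="path", n_macro_states=2, step_size=1.0, edge_length=20.0)
    tree = simulate_division_tree(cfg, st, np.random.default_rng(2))
    for node in tree.internal_nodes():
        g = [st.geodesic(node.state, c.state) for c in node.children]
        assert all(x in (0.0, 1.0) for x in g)
        if not st.is_terminal(node.state):
            assert sorted(g) == [0.0, 1.0]


def test_division_tree_state_irreversibility():
    ds = simulate_dataset(SimConfig(n_cells=128, seed=3))
    st = ds.state_tree
    for parent, child in ds.true_tree.edges():
        assert st.geodesic(parent.state, child.state) != INF


# ---------------------------------------------------------------------------
# simulate_barcodes
# ---------------------------------------------------------------------------


def test_barcodes_mu_zero_all_unedited():
    ds = simulate_dataset(SimConfig(n_cells=64, mu=0.0, seed=4))
    assert all(
        e == UNMUTATED for row in ds.character_matrix.entries for e in row
    )


def test_barcodes_mu_one_saturates_first_edge():
    ds = simulate_dataset(SimConfig(n_cells=32, mu=1.0, dropout=False, seed=5))
    assert not any(
        e == UNMUTATED for row in ds.character_matrix.entries for e in row
    )


def test_barcode_site_trajectories_are_irreversible():
    # along every root-to-leaf path each site reads "0"* allele* "-"*
    ds = simulate_dataset(SimConfig(n_cells=128, mu=0.2, seed=6))
    leaves = ds.true_tree.leaves()
    for leaf in leaves[::5]:
        path = [leaf]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        path.reverse()
        for site in range(ds.config.n_targets):
            traj = [node.barcode[site] for node in path]
            phase = 0  # 0 = unmutated, 1 = mutated allele, 2 = dropped out
            for t in traj:
                if t == UNMUTATED:
                    assert phase == 0, traj
                elif t == DROPOUT:
                    phase = 2
                else:
                    assert phase <= 1, traj
                    phase = 1
            # at most one distinct allele per site per lineage
            alleles = {t for t in traj if t not in (UNMUTATED, DROPOUT)}
            assert len(alleles) <= 1, traj


def test_excision_rule_on_realized_edges():
    # find edges with >= 2 new cuts and check the strict-interior excision
    checked = 0
    for seed in (7, 17, 27):
        cfg = SimConfig(n_cells=128, mu=0.3, seed=seed)
        ds = simulate_dataset(cfg)
        checked += check_excision_edges(ds, cfg)
    assert checked > 5


def check_excision_edges(ds, cfg) -> int:
    checked = 0
    for parent, child in ds.true_tree.edges():
        new_cuts = [
            i
            for i in range(cfg.n_targets)
            if parent.barcode[i] == UNMUTATED
            and child.barcode[i] not in (UNMUTATED, DROPOUT)
        ]
        dropped = [
            i
            for i in range(cfg.n_targets)
            if parent.barcode[i] != DROPOUT and child.barcode[i] == DROPOUT
        ]
        if len(new_cuts) >= 2:
            lo, hi = min(new_cuts), max(new_cuts)
            # every newly dropped site lies strictly between the outermost cuts
            for i in dropped:
                assert lo < i < hi
            # all parent-unmutated/mutated sites strictly inside became "-"
            for i in range(lo + 1, hi):
                assert child.barcode[i] == DROPOUT
            checked += 1
        elif dropped:
            pytest.fail("dropout without two new cuts on one edge")
    return checked


def test_dropout_is_inherited():
    ds = simulate_dataset(SimConfig(n_cells=128, mu=0.3, seed=8))
    for parent, child in ds.true_tree.edges():
        for i in range(ds.config.n_targets):
            if parent.barcode[i] == DROPOUT:
                assert child.barcode[i] == DROPOUT


# ---------------------------------------------------------------------------
# simulate_expression
# ---------------------------------------------------------------------------


def test_expression_centroid_distance_tracks_geodesic():
    # property of the random walk: centroid distance grows with geodesic
    pairs = []
    for seed in range(20):
        cfg = SimConfig(
            n_cells=4,  # unused by the dict-source path below
            n_genes=400,
            nb_size=50.0,
            lib_sigma=0.0,
            seed=seed,
        )
        st = make_state_tree(shape="path", n_macro_states=2, step_size=1.0, edge_length=9.0)
        states = {f"cell_{s}": s for s in st.states()}
        em = simulate_expression(states, st, cfg, np.random.default_rng(seed))
        logx = np.log1p(em.counts)
        root_row = em.cell_ids.index(f"cell_{st.root}")
        for s in st.states():
            if s == st.root:
                continue
            row = em.cell_ids.index(f"cell_{s}")
            pairs.append(
                (st.geodesic(st.root, s), np.linalg.norm(logx[row] - logx[root_row]))
            )
    rho = spearmanr([p[0] for p in pairs], [p[1] for p in pairs]).statistic
    assert rho > 0.5


def test_expression_dict_source_is_state_conditional():
    st = make_state_tree(shape="path", n_macro_states=2, step_size=1.0, edge_length=2.0)
    cfg = SimConfig(n_cells=4, n_genes=50, seed=0)
    states = {"a": st.root, "b": st.root}
    em = simulate_expression(states, st, cfg, np.random.default_rng(0))
    assert em.counts.shape == (2, 50)
    assert np.all(em.counts >= 0)


def test_expression_heritable_siblings_are_neighbors():
    # with the division-tree source, siblings are closer in expression than
    # random pairs on average
    ds = simulate_dataset(SimConfig(n_cells=128, seed=9))
    em = ds.expression
    logx = np.log1p(em.counts)
    idx = {c: i for i, c in enumerate(em.cell_ids)}
    sib, rand = [], []
    rng = np.random.default_rng(0)
    leaves = ds.true_tree.leaves()
    for node in ds.true_tree.internal_nodes():
        a, b = node.children
        if a.is_leaf and b.is_leaf:
            sib.append(np.linalg.norm(logx[idx[a.name]] - logx[idx[b.name]]))
            i, j = rng.integers(len(leaves), size=2)
            rand.append(
                np.linalg.norm(logx[idx[leaves[i].name]] - logx[idx[leaves[j].name]])
            )
    assert np.mean(sib) < np.mean(rand)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def test_dataset_determinism():
    cfg = SimConfig(n_cells=128, mu=0.1, seed=1)
    d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
    assert d1.character_matrix.cell_ids == d2.character_matrix.cell_ids
    assert d1.character_matrix.barcodes() == d2.character_matrix.barcodes()
    np.testing.assert_array_equal(d1.expression.counts, d2.expression.counts)
    assert d1.true_tree.to_newick(with_states=True) == d2.true_tree.to_newick(
        with_states=True
    )


def test_dataset_invariants():
    ds = simulate_dataset(SimConfig(n_cells=64, seed=10))
    # leaf barcodes in the matrix equal leaf barcodes on the truth tree
    by_name = {l.name: l.barcode for l in ds.true_tree.leaves()}
    for cell, row in zip(ds.character_matrix.cell_ids, ds.character_matrix.barcodes()):
        assert by_name[cell] == row
    assert set(ds.state_assignment) == set(ds.character_matrix.cell_ids)
    assert ds.expression.cell_ids == ds.character_matrix.cell_ids


def test_dataset_cell_order_is_not_traversal_order():
    # the emitted row order must not leak true sibling adjacency
    ds = simulate_dataset(SimConfig(n_cells=256, seed=0))
    traversal = [l.name for l in ds.true_tree.leaves()]
    assert ds.character_matrix.cell_ids != traversal
    assert sorted(ds.character_matrix.cell_ids) == sorted(traversal)


def test_qr_recount_matches_independent_traversal():
    ds = simulate_dataset(SimConfig(n_cells=128, mu=0.15, seed=11))
    got = reconstruction_potential(ds.true_tree)
    stack, unmut, edges = [ds.true_tree.root], 0, 0
    while stack:
        node = stack.pop()
        for c in node.children:
            edges += 1
            if tuple(node.barcode) == tuple(c.barcode):
                unmut += 1
            stack.append(c)
    assert got == unmut / edges


def test_save_dataset_writes_everything(tmp_path):
    ds = simulate_dataset(SimConfig(n_cells=32, seed=12))
    out = tmp_path / "ds"
    save_dataset(ds, str(out))
    for name in (
        "true_tree.nwk",
        "barcodes.tsv",
        "expression.csv",
        "states.tsv",
        "state_tree.nwk",
        "all_barcodes.tsv",
        "config.json",
    ):
        assert (out / name).exists()
    cfg = json.loads((out / "config.json").read_text())
    assert cfg["n_cells"] == 32
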