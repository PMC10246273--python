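"""Shared helpers: tiny tree builders and exhaustive-enumeration oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from linrace.lineage_data import LineageTree, Node


def node_from(spec) -> Node:
    """Build a Node from nested tuples; strings become leaves."""
    if isinstance(spec, str):
        return Node(name=spec)
    node = Node()
    for child in spec:
        node.add_child(node_from(child))
    return node


def tree_from(spec) -> LineageTree:
    """Build a LineageTree from nested tuples, e.g. (("a","b"),("c","d"))."""
    return LineageTree(node_from(spec))


def enumerate_rooted_topologies(leaves: list[str]) -> list[LineageTree]:
    """All (2n-3)!! rooted binary topologies over the given leaves.

    Sequential insertion: each new leaf is attached above every node of every
    partial topology (including above the root), which generates each rooted
    binary topology exactly once.
    """
    trees = [LineageTree(Node(name=leaves[0]))]
    for leaf in leaves[1:]:
        nxt = []
        for t in trees:
            for i in range(len(t.nodes())):
                new = t.copy()
                target = new.nodes()[i]
                joint = Node()
                parent = target.parent
                if parent is None:
                    new.root = joint
                else:
                    parent.children[parent.children.index(target)] = joint
                    joint.parent = parent
                joint.add_child(target)
                joint.add_child(Node(name=leaf))
                nxt.append(new)
        trees = nxt
    return trees


def topology_key(tree: LineageTree) -> frozenset:
    """Canonical key of a rooted topology (set of leaf-sets of all clades)."""
    key = set()
    below = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        key.add(below[id(node)])
    return frozenset(key)


def brute_force_nye(t1: LineageTree, t2: LineageTree) -> float:
    """Nye similarity by exhaustive enumeration of injective split alignments."""
    from linrace.tree_metrics import split_score, splits

    s1, s2 = list(splits(t1)), list(splits(t2))
    if not s1 and not s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    small, big = (s1, s2) if len(s1) <= len(s2) else (s2, s1)
    best = 0.0
    for perm in itertools.permutations(range(len(big)), len(small)):
        best = max(best, sum(split_score(small[i], big[j]) for i, j in enumerate(perm)))
    return best / max(len(s1), len(s2))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
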