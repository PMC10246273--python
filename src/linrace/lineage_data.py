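"""Core data types and I/O for lineage-tracing analyses.

The package works with three kinds of observations on the same set of cells:

* a *character matrix* of CRISPR lineage barcodes — one row per cell, one
  column per editable target site, each entry ``"0"`` (unmutated), ``"-"``
  (dropout) or an arbitrary token naming a mutation outcome;
* an *expression matrix* of non-negative gene counts;
* rooted trees (cell lineage trees and cell state trees) in Newick format.

Mutation tokens are categorical: two entries are compared by string equality
only, never by magnitude or position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.io import mmread

UNMUTATED = "0"
DROPOUT = "-"

#: Separator used to serialize a node's state into its Newick label,
#: e.g. ``cell_17|S3``.  Chosen because it needs no quoting in Newick.
STATE_SEP = "|"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a structural invariant."""


class AlignmentError(ValueError):
    """Raised when paired matrices disagree on the set of cells."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Node:
    """A node of a rooted lineage tree.

    Attributes
    ----------
    name:
        Cell id for leaves; optional label for internal nodes.
    state:
        Optional discrete cell-state label.
    barcode:
        Optional tuple of target-site entries (simulated truth carries one on
        every node).
    length:
        Branch length of the edge above this node (1.0 = one division).
    """

    __slots__ = ("name", "state", "barcode", "length", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        state: str | None = None,
        barcode: tuple[str, ...] | None = None,
        length: float = 1.0,
    ) -> None:
        self.name = name
        self.state = state
        self.barcode = barcode
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<Node {self.name!r} {kind} state={self.state!r}>"


@dataclass
class LineageTree:
    """A rooted tree whose leaves are cells.

    Internal nodes may carry inferred states and (for simulated data)
    ancestral barcodes.  Branch lengths default to one division per edge;
    the topology-based metrics ignore them.
    """

    root: Node

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def edges(self) -> list[tuple[Node, Node]]:
        """Parent→child pairs, in preorder."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.preorder() if n.is_leaf)

    def is_bifurcating(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.internal_nodes())

    def copy(self) -> "LineageTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.state, node.barcode, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return LineageTree(clone(self.root))

    # -- Newick serialization ------------------------------------------------

    def to_newick(self, with_states: bool = False, with_lengths: bool = True) -> str:
        def label(node: Node) -> str:
            name = node.name or ""
            if with_states and node.state is not None:
                name = f"{name}{STATE_SEP}{node.state}"
            return name

        def render(node: Node) -> str:
            if node.is_leaf:
                core = label(node)
            else:
                inner = ",".join(render(c) for c in node.children)
                core = f"({inner}){label(node)}"
            if with_lengths and node.parent is not None:
                core += f":{node.length:g}"
            return core

        return render(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> LineageTree:
    def convert(dnode: dendropy.Node) -> Node:
        raw = None
        if dnode.taxon is not None:
            raw = dnode.taxon.label
        elif dnode.label is not None:
            raw = dnode.label
        name, state = raw, None
        if raw is not None and STATE_SEP in raw:
            name, state = raw.split(STATE_SEP, 1)
            name = name or None
        node = Node(
            name=name,
            state=state,
            length=dnode.edge.length if dnode.edge.length is not None else 1.0,
        )
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return LineageTree(convert(dtree.seed_node))


def parse_newick(text: str) -> LineageTree:
    """Parse a Newick string into a :class:`LineageTree`.

    Node labels of the form ``name|state`` are split into a name and a state
    label; plain labels become names with no state.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"could not parse Newick input: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path: str) -> LineageTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: LineageTree, path: str, with_states: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(with_states=with_states) + "\n")


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Lineage barcodes for ``N`` cells over ``M`` target sites."""

    cell_ids: list[str]
    target_ids: list[str]
    entries: np.ndarray  # (N, M) array of str objects

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=object)
        n, m = self.entries.shape
        if n != len(self.cell_ids):
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids but {n} barcode rows"
            )
        if m != len(self.target_ids):
            raise ValidationError(
                f"{len(self.target_ids)} target ids but {m} barcode columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = sorted(
                c for c in set(self.cell_ids) if self.cell_ids.count(c) > 1
            )
            raise ValidationError(f"duplicate cell ids: {dupes}")

    @property
    def n_cells(self) -> int:
        return self.entries.shape[0]

    @property
    def n_targets(self) -> int:
        return self.entries.shape[1]

    def row(self, cell_id: str) -> tuple[str, ...]:
        return tuple(self.entries[self.cell_ids.index(cell_id)])

    def barcodes(self) -> list[tuple[str, ...]]:
        return [tuple(r) for r in self.entries]


def read_character_matrix(path: str, dialect: str = "tsv") -> CharacterMatrix:
    """Read a cell × target barcode table.

    The first column holds cell ids; the header row holds target names.  All
    entries are normalized to strings so that mutation tokens stay
    categorical.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, header=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty barcode file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed barcode table: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no target columns found")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise FormatError(
            f"{path}: ragged or missing entries for cells {list(bad[:5])}"
        )
    return CharacterMatrix(
        cell_ids=[str(c) for c in df.index],
        target_ids=[str(t) for t in df.columns],
        entries=df.to_numpy(dtype=object),
    )


def write_character_matrix(cm: CharacterMatrix, path: str) -> None:
    df = pd.DataFrame(cm.entries, index=cm.cell_ids, columns=cm.target_ids)
    df.to_csv(path, sep="\t", index_label="cell_id")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Non-negative cell × gene counts."""

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray  # (N, G) float array

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.gene_ids)} genes"
            )
        if np.any(self.counts < 0):
            raise ValidationError("negative expression counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def aligned_to(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        """Reorder rows to match ``cell_ids``; error on missing cells."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in index]
        if missing:
            raise AlignmentError(
                f"cells absent from expression matrix: {missing[:10]}"
            )
        rows = [index[c] for c in cell_ids]
        return ExpressionMatrix(
            cell_ids=list(cell_ids),
            gene_ids=list(self.gene_ids),
            counts=self.counts[rows],
        )


def read_expression(
    path: str,
    format: str = "csv",
    cell_ids_path: str | None = None,
    gene_ids_path: str | None = None,
) -> ExpressionMatrix:
    """Read a cell × gene count matrix.

    ``csv`` expects a dense table with cell ids in the first column and gene
    names in the header.  ``mtx`` expects a Matrix Market file (cells × genes)
    plus one-id-per-line companion files for rows and columns.
    """
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0, header=0)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{path}: empty expression file") from exc
        counts = df.to_numpy(dtype=float)
        return ExpressionMatrix(
            cell_ids=[str(c) for c in df.index],
            gene_ids=[str(g) for g in df.columns],
            counts=counts,
        )
    if format == "mtx":
        if cell_ids_path is None or gene_ids_path is None:
            raise ValueError("mtx format requires cell_ids_path and gene_ids_path")
        mat = mmread(path)
        counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        with open(cell_ids_path) as fh:
            cells = [line.strip() for line in fh if line.strip()]
        with open(gene_ids_path) as fh:
            genes = [line.strip() for line in fh if line.strip()]
        return ExpressionMatrix(cell_ids=cells, gene_ids=genes, counts=counts)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(em: ExpressionMatrix, path: str) -> None:
    pd.DataFrame(em.counts, index=em.cell_ids, columns=em.gene_ids).to_csv(
        path, index_label="cell_id"
    )


# ---------------------------------------------------------------------------
# State assignments
# ---------------------------------------------------------------------------

StateAssignment = dict  # cell/node id -> state label


def read_states(path: str) -> dict[str, str]:
    """Read a two-column TSV of ``cell_id<TAB>state``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "state"], dtype=str)
    if df["state"].isna().any():
        raise FormatError(f"{path}: missing state labels")
    return dict(zip(df["cell_id"], df["state"]))


def write_states(states: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for cell, state in states.items():
            fh.write(f"{cell}\t{state}\n")
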