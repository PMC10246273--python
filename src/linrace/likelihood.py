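"""Likelihood of a candidate lineage (sub)tree under the asymmetric-division
model.

The score of a bifurcating tree with states on every node is a weighted sum
of three log-likelihood terms:

* **state transition** — each edge's state change is scored by the empirical
  frequency of its state-tree geodesic among all (finite-geodesic) edges of
  the candidate tree; an edge whose transition is impossible on the state
  tree (infinite geodesic) incurs a flat log-space penalty (default −50);
* **asymmetric division** — each internal node contributes ``log(1 − pa)``
  if its two daughters share a state (symmetric division) and ``log(pa)``
  otherwise, where ``pa`` is the asymmetric division rate;
* **neighbor distance** — each cherry of measured cells contributes the log
  diffusion-map transition probability between the two cells' expression
  profiles, favoring trees whose siblings are transcriptomic neighbors.

total = L_transition + λ1 · L_asymmetric + λ2 · L_neighbor, all in log space,
so the score is finite for every valid tree.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .lineage_data import LineageTree
from .state_model import CellStateTree, ExpressionEmbedding, INF

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-300  # guards log of underflowed kernel values


@dataclass
class LikelihoodParams:
    """Hyperparameters of the tree likelihood.

    ``lambda1`` and ``lambda2`` weight the asymmetric-division and
    neighbor-distance terms (defaults 10 and 1); ``pa`` is the asymmetric
    division rate (default 0.8, strictly inside (0,1) so both branches have
    finite logs); ``unreachable_penalty`` is added per edge whose state
    transition is impossible on the state tree; ``sigma`` is the RBF
    bandwidth, or ``"median"`` for the median of nonzero pairwise embedding
    distances.
    """

    lambda1: float = 10.0
    lambda2: float = 1.0
    pa: float = 0.8
    unreachable_penalty: float = -50.0
    sigma: float | str = "median"

    def __post_init__(self) -> None:
        if not (0.0 < self.pa < 1.0):
            raise ValueError("pa must be strictly inside (0, 1)")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be non-negative")


@dataclass
class KernelCache:
    """Precomputed RBF kernel and diffusion normalizers over all measured
    cells.

    ``K[i, j] = exp(-||x_i - x_j||² / (2σ²))`` with ``K[i, i] = 1``;
    ``Z(x_i) = Σ_k K[i, k]`` (including self); the per-cell normalizer
    ``Ẑ(x_i) = Σ_{k≠i} K[i, k] / (Z(x_i) Z(x_k))`` makes the transition
    probabilities ``P(x_i → x_j) = K[i, j] / (Ẑ(x_i) Z(x_i) Z(x_j))`` sum
    to one over ``j ≠ i``.  Topology-independent, so it is built once per
    dataset and shared by every subtree search.
    """

    cell_ids: list[str]
    K: np.ndarray
    Z: np.ndarray
    Zhat: np.ndarray
    sigma: float
    coords: np.ndarray = None  # embedding used to build the kernel
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {c: i for i, c in enumerate(self.cell_ids)}

    def pnd(self, a: str, b: str) -> float:
        """Diffusion transition probability from cell ``a`` to cell ``b``."""
        i, j = self.index[a], self.index[b]
        return self.K[i, j] / (self.Zhat[i] * self.Z[i] * self.Z[j])

    def log_pnd_symmetric(self, a: str, b: str) -> float:
        """Geometric-mean log transition probability of an unordered pair."""
        return 0.5 * (
            math.log(max(self.pnd(a, b), _LOG_FLOOR))
            + math.log(max(self.pnd(b, a), _LOG_FLOOR))
        )


def build_kernel_cache(
    emb: ExpressionEmbedding, params: LikelihoodParams | None = None
) -> KernelCache:
    """Build the dense RBF kernel and its diffusion normalizers.

    With the default ``sigma="median"`` rule the bandwidth is the median of
    the nonzero pairwise Euclidean distances in the embedding; if every pair
    coincides the bandwidth falls back to 1 with a warning.
    """
    params = params or LikelihoodParams()
    x = np.asarray(emb.coords, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("kernel cache requires at least 2 cells")
    dists = pdist(x)
    if params.sigma == "median":
        nz = dists[dists > 0]
        if nz.size == 0:
            logger.warning("all embedding rows identical; using sigma=1")
            sigma = 1.0
        else:
            sigma = float(np.median(nz))
    else:
        sigma = float(params.sigma)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
    sq = squareform(dists) ** 2
    K = np.exp(-sq / (2.0 * sigma**2))
    Z = K.sum(axis=1)
    ratio = K / np.outer(Z, Z)
    Zhat = ratio.sum(axis=1) - np.diag(ratio)
    return KernelCache(cell_ids=list(emb.cell_ids), K=K, Z=Z, Zhat=Zhat, sigma=sigma, coords=x)


# ---------------------------------------------------------------------------
# Likelihood terms
# ---------------------------------------------------------------------------


def _edge_geodesics(tree: LineageTree, st: CellStateTree) -> list[float]:
    out = []
    for parent, child in tree.edges():
        if parent.state is None or child.state is None:
            raise ValueError("every node needs a state; run ancestral inference first")
        out.append(st.geodesic(parent.state, child.state))
    return out


def transition_distribution(
    tree: LineageTree, st: CellStateTree
) -> dict[float, float]:
    """Empirical distribution of finite state-tree geodesics over the tree's
    edges.

    Edges whose transition is unreachable (infinite geodesic) are excluded
    from both numerator and denominator; they are handled by the penalty in
    :func:`state_transition_loglik`.  A tree with no finite-geodesic edge
    yields an empty distribution.
    """
    finite = [g for g in _edge_geodesics(tree, st) if g != INF]
    if not finite:
        return {}
    counts = Counter(finite)
    total = len(finite)
    return {g: c / total for g, c in counts.items()}


def state_transition_loglik(
    tree: LineageTree, st: CellStateTree, params: LikelihoodParams
) -> float:
    dist = transition_distribution(tree, st)
    total = 0.0
    for g in _edge_geodesics(tree, st):
        if g == INF:
            total += params.unreachable_penalty
        else:
            total += math.log(dist[g])
    return total


def asymmetric_division_loglik(tree: LineageTree, params: LikelihoodParams) -> float:
    log_sym = math.log(1.0 - params.pa)
    log_asym = math.log(params.pa)
    total = 0.0
    for node in tree.internal_nodes():
        if len(node.children) != 2:
            raise ValueError("asymmetric-division likelihood requires a binary tree")
        s1, s2 = node.children[0].state, node.children[1].state
        if s1 is None or s2 is None:
            raise ValueError("children lack states; run ancestral inference first")
        total += log_sym if s1 == s2 else log_asym
    return total


def estimate_pa(tree: LineageTree, default: float = 0.8) -> float:
    """Estimate the asymmetric division rate from a tree with states.

    Returns the fraction of internal nodes whose daughters differ in state,
    clamped to [0.01, 0.99] so both likelihood branches stay finite.
    """
    internal = tree.internal_nodes()
    if not internal:
        logger.warning("no internal nodes; returning default pa=%.2f", default)
        return default
    asym = sum(
        1 for n in internal if n.children[0].state != n.children[1].state
    )
    return min(0.99, max(0.01, asym / len(internal)))


def neighbor_distance_loglik(tree: LineageTree, kc: KernelCache) -> float:
    """Sum of log diffusion transition probabilities over leaf-leaf cherries.

    Only sibling pairs where both children are measured leaf cells
    contribute; pairs involving internal nodes have no expression profile
    and contribute nothing.
    """
    total = 0.0
    for node in tree.internal_nodes():
        a, b = node.children[0], node.children[1]
        if a.is_leaf and b.is_leaf:
            for leaf in (a, b):
                if leaf.name not in kc.index:
                    raise KeyError(f"leaf cell {leaf.name!r} absent from kernel cache")
            total += kc.log_pnd_symmetric(a.name, b.name)
    return total


def total_loglik(
    tree: LineageTree,
    st: CellStateTree,
    kc: KernelCache | None,
    params: LikelihoodParams,
) -> float:
    """Weighted total log-likelihood of a stated, bifurcating tree."""
    total = state_transition_loglik(tree, st, params)
    total += params.lambda1 * asymmetric_division_loglik(tree, params)
    if params.lambda2 != 0.0:
        if kc is None:
            raise ValueError("kernel cache required when lambda2 != 0")
        total += params.lambda2 * neighbor_distance_loglik(tree, kc)
    return total
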