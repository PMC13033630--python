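"""Correlation-guided association graph with first- and second-order context.

Pairwise Pearson correlation of activity profiles is binarized at a strict
threshold tau (default 0.6) to give a symmetric, zero-diagonal adjacency A.
Squaring A counts length-two paths; the first-order neighborhood N1(i) is
the set of direct neighbors and N2(i) the set of nodes reachable by at
least one two-hop path (excluding i itself).  N1 and N2 may overlap; the
union C(i) = N1 ∪ N2 is the context set used downstream.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationGraph",
    "CorrelationGraphBuilder",
    "pearson_similarity",
    "binarize",
    "build_neighborhoods",
    "restrict_to_ppi",
]

DEFAULT_TAU = 0.6


def pearson_similarity(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between all row pairs, with Sim = 0 wherever a
    row has zero variance (activity filtering can zero out whole rows, where
    correlation is undefined; 0 = "no association" is the convention)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 2:
        raise ValueError("expected an (N, M) matrix with M >= 2")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    unit = centered / safe[:, None]
    sim = unit @ unit.T
    sim[~ok, :] = 0.0
    sim[:, ~ok] = 0.0
    np.clip(sim, -1.0, 1.0, out=sim)
    # exact diagonal for rows with variance; zero-variance convention elsewhere
    np.fill_diagonal(sim, np.where(ok, 1.0, 0.0))
    return sim


def binarize(sim: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """a_ij = 1 iff Sim(i,j) > tau (strict) and i != j."""
    if not -1.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (-1, 1), got {tau}")
    sim = np.asarray(sim, dtype=np.float64)
    adj = (sim > tau).astype(np.int64)
    np.fill_diagonal(adj, 0)
    return adj


@dataclasses.dataclass
class CorrelationGraph:
    adjacency: np.ndarray       # binary (N, N), symmetric, zero diagonal
    second_order: np.ndarray    # A @ A, integer
    n1: dict[int, list[int]]    # direct neighbors, sorted
    n2: dict[int, list[int]]    # two-hop reachable (j != i), sorted
    tau: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def context_sets(self) -> dict[int, list[int]]:
        """C(i) = N1(i) ∪ N2(i), sorted."""
        return {i: sorted(set(self.n1[i]) | set(self.n2[i]))
                for i in range(self.n_nodes)}

    def masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(first-order, second-order, union-context) boolean masks."""
        m1 = self.adjacency > 0
        m2 = self.second_order > 0
        np.fill_diagonal(m2, False)
        return m1, m2, m1 | m2


def build_neighborhoods(adjacency: np.ndarray, tau: float = DEFAULT_TAU) -> CorrelationGraph:
    """Derive A², N1 and N2 from a symmetric binary adjacency."""
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adjacency) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    adjacency = adjacency.astype(np.int64)
    a2 = adjacency @ adjacency
    n = adjacency.shape[0]
    n1 = {i: np.flatnonzero(adjacency[i]).tolist() for i in range(n)}
    n2 = {}
    for i in range(n):
        js = np.flatnonzero(a2[i] > 0)
        n2[i] = js[js != i].tolist()
    return CorrelationGraph(adjacency, a2, n1, n2, tau)


def restrict_to_ppi(graph: CorrelationGraph, edges, n_nodes: int | None = None,
                    mode: str = "correlation_only") -> CorrelationGraph:
    """Optionally intersect the correlation adjacency with a PPI edge list.

    ``mode='correlation_only'`` (default) returns the graph unchanged; with
    ``'ppi_intersect'`` an edge survives only if it is also a PPI edge, and
    A²/N1/N2 are recomputed.  Edges naming unknown nodes are skipped with a
    logged count.
    """
    if mode == "correlation_only":
        return graph
    if mode != "ppi_intersect":
        raise ValueError(f"unknown graph mode {mode!r}")
    n = n_nodes or graph.n_nodes
    ppi = np.zeros((n, n), dtype=np.int64)
    skipped = 0
    for i, j in edges:
        if 0 <= i < n and 0 <= j < n:
            ppi[i, j] = ppi[j, i] = 1
        else:
            skipped += 1
    if skipped:
        logger.warning("restrict_to_ppi: skipped %d edges with unknown node indices", skipped)
    return build_neighborhoods(graph.adjacency * ppi, tau=graph.tau)


class CorrelationGraphBuilder:
    """Build a :class:`CorrelationGraph` from an activity matrix.

    Parameters
    ----------
    tau : float, default 0.6
        Strict binarization threshold on the Pearson similarity.
    mode : {'correlation_only', 'ppi_intersect'}
        Whether to intersect the correlation edges with a supplied PPI
        edge list.
    """

    def __init__(self, tau: float = DEFAULT_TAU, mode: str = "correlation_only"):
        self.tau = tau
        self.mode = mode

    def get_params(self, deep: bool = True) -> dict:
        return {"tau": self.tau, "mode": self.mode}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, ppi_edges=None):
        X = np.asarray(X, dtype=np.float64)
        self.similarity_ = pearson_similarity(X)
        graph = build_neighborhoods(binarize(self.similarity_, self.tau), tau=self.tau)
        if self.mode == "ppi_intersect":
            graph = restrict_to_ppi(graph, ppi_edges if ppi_edges is not None else [],
                                    n_nodes=X.shape[0], mode=self.mode)
        self.graph_ = graph
        return self

    def fit_transform(self, X, y=None, ppi_edges=None) -> CorrelationGraph:
        return self.fit(X, ppi_edges=ppi_edges).graph_
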