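"""Partial-correlation network estimation with significance sparsification.

The edge weight between two variables is their partial correlation given
all remaining variables, obtained from the inverse of the sample
correlation matrix (the precision matrix P):

    r_ij.rest = -P_ij / sqrt(P_ii * P_jj)

Each partial correlation is tested against zero with the t transform
t = r * sqrt(df / (1 - r^2)) on df = n - k - 2 degrees of freedom, where
k is the number of conditioned variables (15 for the 17-node schema).
For multivariate-normal data this df convention makes the null p-values
exactly uniform. Edges are retained when p < alpha; the deliberately
liberal default alpha = 0.25 trades specificity for sensitivity, on the
view that absence of an edge is not evidence the association is exactly
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortTable

#: correlation-matrix condition number above which estimation is refused
CONDITION_LIMIT = 1e10

DEFAULT_ALPHA = 0.25


@dataclass(frozen=True)
class PartialCorrelationResult:
    """Symmetric partial-correlation matrix with matched p-values."""

    r: np.ndarray  # (p, p), diagonal 1
    p: np.ndarray  # (p, p), diagonal 0
    n: int  # sample size
    k: int  # number of conditioned variables (p - 2)

    @property
    def df(self) -> int:
        return self.n - self.k - 2


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected graph with signed edge weights over named nodes.

    ``edges`` maps node-index pairs (i < j) to (weight, p_value); for
    graphs not produced by the estimator p_value may be ``None``.
    ``node_meta`` optionally carries per-node attribute dicts (dimension,
    centralities, community id) for serialization.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[int, int], tuple[float, float | None]] = field(
        default_factory=dict
    )
    node_meta: tuple[dict, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for (i, j) in self.edges:
            if not (0 <= i < j < n):
                raise ValueError(f"invalid edge ({i}, {j}) for {n} nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric signed-weight adjacency matrix."""
        n = self.n_nodes
        w = np.zeros((n, n))
        for (i, j), (wt, _) in self.edges.items():
            w[i, j] = w[j, i] = wt
        return w

    def neighbors(self, i: int) -> list[int]:
        return sorted(
            {j for (a, b) in self.edges for j in (a, b) if i in (a, b)} - {i}
        )

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    @staticmethod
    def from_weight_matrix(
        w: np.ndarray, nodes: tuple[str, ...] | None = None
    ) -> "WeightedGraph":
        w = np.asarray(w, dtype=float)
        n = w.shape[0]
        names = nodes or tuple(f"v{i}" for i in range(n))
        edges = {
            (i, j): (float(w[i, j]), None)
            for i in range(n)
            for j in range(i + 1, n)
            if w[i, j] != 0.0
        }
        return WeightedGraph(tuple(names), edges)


class EstimationError(ValueError):
    """Raised when the correlation matrix cannot support estimation."""


def _check_invertible(corr: np.ndarray, names: list[str]) -> None:
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[0] <= 0 or eigvals[-1] / eigvals[0] > CONDITION_LIMIT:
        loadings = np.abs(eigvecs[:, 0])
        involved = [names[i] for i in np.where(loadings > 0.3)[0]] or names
        raise EstimationError(
            "correlation matrix is numerically singular; near-collinear "
            f"variable set: {', '.join(involved)}"
        )


def partial_correlations(cohort: CohortTable) -> PartialCorrelationResult:
    """Estimate all pairwise partial correlations, conditioning each pair
    on every other variable, with two-sided p-values.

    Requires n >= 20 (so df = n - 15 - 2 >= 3 for the 17-node schema) and
    a numerically invertible correlation matrix.
    """
    x = cohort.values
    n, p = x.shape
    k = p - 2
    if n - k - 2 < 3:
        raise EstimationError(
            f"n={n} gives df={n - k - 2} (< 3) with {k} conditioned variables"
        )
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [cohort.schema.names[i] for i in np.where(sd == 0)[0]]
        raise EstimationError(f"constant column(s): {', '.join(const)}")

    corr = np.corrcoef(x, rowvar=False)
    _check_invertible(corr, cohort.schema.names)
    prec = np.linalg.inv(corr)

    d = np.sqrt(np.diag(prec))
    r = -prec / np.outer(d, d)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)

    df = n - k - 2
    off = ~np.eye(p, dtype=bool)
    t = np.zeros_like(r)
    t[off] = r[off] * np.sqrt(df / np.maximum(1.0 - r[off] ** 2, 1e-300))
    pvals = np.zeros_like(r)
    pvals[off] = 2.0 * stats.t.sf(np.abs(t[off]), df)
    return PartialCorrelationResult(r=r, p=pvals, n=n, k=k)


def edge_p_threshold(n: int, k: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Smallest |partial correlation| retained by the p < alpha rule.

    Inverts the t transform at the two-sided critical value for
    df = n - k - 2.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = n - k - 2
    if df < 1:
        raise ValueError(f"df = n - k - 2 = {df} < 1")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def sparsify(
    pc: PartialCorrelationResult,
    alpha: float = DEFAULT_ALPHA,
    nodes: tuple[str, ...] | None = None,
    node_meta: tuple[dict, ...] | None = None,
) -> WeightedGraph:
    """Keep exactly the edges with p < alpha (strict); all nodes stay,
    isolated or not. Edge weight is the signed partial correlation."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    n = pc.r.shape[0]
    names = nodes or tuple(f"v{i}" for i in range(n))
    edges = {
        (i, j): (float(pc.r[i, j]), float(pc.p[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if pc.p[i, j] < alpha
    }
    return WeightedGraph(tuple(names), edges, node_meta=node_meta)


def estimate_stratum_network(
    cohort: CohortTable, alpha: float = DEFAULT_ALPHA
) -> WeightedGraph:
    """Full estimate-then-threshold pipeline for one stratum."""
    pc = partial_correlations(cohort)
    meta = tuple(
        {"label": e.label, "dimension": e.dimension, "mtype": e.mtype}
        for e in cohort.schema
    )
    return sparsify(pc, alpha, nodes=tuple(cohort.schema.names), node_meta=meta)
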