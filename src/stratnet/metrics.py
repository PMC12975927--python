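"""Global and node-level graph statistics.

Conventions match the ones common in network visualization software:

* distances are unweighted hops (partial-correlation weights are
  similarities, not costs, and reported diameters are integers);
* eigenvector centrality runs on absolute weights and is scaled so the
  maximum score is exactly 1;
* closeness uses the reachable-only sum with the Wasserman–Faust
  component correction, so isolated nodes score 0;
* the clustering coefficient is the usual triangle density on the
  unweighted topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .pcorr import WeightedGraph

EIG_TOL = 1e-8
EIG_MAX_ITER = 1000


def to_networkx(graph: WeightedGraph) -> nx.Graph:
    """Signed-weight networkx view of a :class:`WeightedGraph`."""
    g = nx.Graph()
    for i, name in enumerate(graph.nodes):
        attrs = dict(graph.node_meta[i]) if graph.node_meta else {}
        g.add_node(name, **attrs)
    for (i, j), (w, p) in sorted(graph.edges.items()):
        attrs = {"weight": w}
        if p is not None:
            attrs["p_value"] = p
        g.add_edge(graph.nodes[i], graph.nodes[j], **attrs)
    return g


def _topology(graph: WeightedGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from(graph.edges.keys())
    return g


def density(graph: WeightedGraph) -> float:
    """Retained edges over all possible edges, m / (n(n-1)/2)."""
    n = graph.n_nodes
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return graph.n_edges / (n * (n - 1) / 2)


def shortest_path_stats(graph: WeightedGraph) -> tuple[float, int]:
    """(average path length, diameter) on hop distances.

    The average is over all ordered reachable pairs of distinct nodes;
    the diameter is the largest finite distance. A graph with no edges
    has no finite paths and raises.
    """
    if graph.n_nodes < 2:
        raise ValueError("path statistics need at least 2 nodes")
    if graph.n_edges == 0:
        raise ValueError("graph has no edges, hence no finite paths")
    g = _topology(graph)
    total, pairs, diam = 0, 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if d > 0:
                total += d
                pairs += 1
                diam = max(diam, d)
    return total / pairs, diam


def eigenvector_centrality(graph: WeightedGraph) -> np.ndarray:
    """Power iteration on the absolute-weight adjacency matrix.

    Scores are scaled so the maximum is exactly 1. Convergence is
    declared when the largest componentwise change falls below
    ``EIG_TOL``; exceeding ``EIG_MAX_ITER`` iterations raises with the
    residual.
    """
    if graph.n_edges == 0:
        raise ValueError("eigenvector centrality needs at least one edge")
    a = np.abs(graph.weight_matrix())
    n = a.shape[0]
    # shift by an upper bound on the spectral radius: same eigenvectors,
    # but the top eigenvalue strictly dominates in magnitude (bipartite
    # graphs otherwise make the plain iteration oscillate)
    a = a + np.eye(n) * a.sum(axis=1).max()
    x = np.ones(n)
    x /= x.max()
    for _ in range(EIG_MAX_ITER):
        y = a @ x
        m = y.max()
        if m <= 0:
            raise ValueError("iteration collapsed to zero vector")
        y /= m
        resid = np.max(np.abs(y - x))
        x = y
        if resid < EIG_TOL:
            return x
    raise RuntimeError(
        f"power iteration did not converge in {EIG_MAX_ITER} iterations "
        f"(residual {resid:.2e})"
    )


def closeness_centrality(graph: WeightedGraph) -> np.ndarray:
    """Hop-distance closeness with component correction.

    For node v reaching n_r other nodes with total distance S:
    closeness = (n_r / S) * (n_r / (n - 1)); isolated nodes score 0.
    """
    if graph.n_nodes < 2:
        raise ValueError("closeness needs at least 2 nodes")
    g = _topology(graph)
    cc = nx.closeness_centrality(g, wf_improved=True)
    return np.array([cc[i] for i in range(graph.n_nodes)])


def clustering_coefficients(graph: WeightedGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its average.

    C_v = 2 * triangles(v) / (deg(v) * (deg(v) - 1)) on the unweighted
    topology; nodes of degree < 2 get C_v = 0 and are excluded from the
    average (0.0 if no node has degree >= 2).
    """
    if graph.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    g = _topology(graph)
    c = nx.clustering(g)
    per_node = np.array([c[i] for i in range(graph.n_nodes)])
    eligible = [i for i in range(graph.n_nodes) if g.degree(i) >= 2]
    avg = float(per_node[eligible].mean()) if eligible else 0.0
    return per_node, avg


@dataclass(frozen=True)
class ActivationView:
    """Neighborhood of an 'activated' node: which other nodes it reaches
    directly (with signed weights, strongest first) and which it does not."""

    node: str
    activated: tuple[tuple[str, float], ...]  # (name, signed weight)
    deactivated: tuple[str, ...]


def activation_view(graph: WeightedGraph, node: str) -> ActivationView:
    """Partition the other nodes by adjacency to ``node``.

    Activated neighbors are sorted by |weight| descending, ties broken by
    node order; deactivated nodes keep node order.
    """
    if node not in graph.nodes:
        raise KeyError(f"unknown node {node!r}")
    idx = graph.nodes.index(node)
    nbr_w: dict[int, float] = {}
    for (i, j), (w, _) in graph.edges.items():
        if i == idx:
            nbr_w[j] = w
        elif j == idx:
            nbr_w[i] = w
    order = sorted(nbr_w, key=lambda j: (-abs(nbr_w[j]), j))
    activated = tuple((graph.nodes[j], nbr_w[j]) for j in order)
    deactivated = tuple(
        graph.nodes[j]
        for j in range(graph.n_nodes)
        if j != idx and j not in nbr_w
    )
    return ActivationView(node=node, activated=activated, deactivated=deactivated)


def centrality_table(graph: WeightedGraph) -> dict[str, dict[str, float]]:
    """Eigenvector, closeness and clustering per node, with ranks.

    Ranks are 1-based, descending by score; ties keep node (schema)
    order via stable sort.
    """
    eig = eigenvector_centrality(graph)
    clo = closeness_centrality(graph)
    clu, _ = clustering_coefficients(graph)

    def ranks(scores: np.ndarray) -> np.ndarray:
        order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
        r = np.empty(len(scores), dtype=int)
        for rank, i in enumerate(order, start=1):
            r[i] = rank
        return r

    r_eig, r_clo, r_clu = ranks(eig), ranks(clo), ranks(clu)
    return {
        name: {
            "eigenvector": float(eig[i]),
            "closeness": float(clo[i]),
            "clustering": float(clu[i]),
            "eigenvector_rank": int(r_eig[i]),
            "closeness_rank": int(r_clo[i]),
            "clustering_rank": int(r_clu[i]),
        }
        for i, name in enumerate(graph.nodes)
    }
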