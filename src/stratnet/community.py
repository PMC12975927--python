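"""Community detection by modularity optimization (Blondel/Louvain).

Modularity is the standard Newman–Girvan weighted quality

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j)

computed on absolute edge weights (signed-modularity variants are
nonstandard and the common network-visualization implementations take
magnitudes). The Louvain procedure alternates seeded local node moves
with community aggregation until Q stops improving; a fixed seed gives a
fully deterministic partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pcorr import WeightedGraph
from .schema import VariableSchema

_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class CommunityPartition:
    """Flat node -> community assignment with its modularity."""

    assignment: tuple[int, ...]  # community id per node, contiguous from 0
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment))

    def members(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_communities)]
        for i, c in enumerate(self.assignment):
            out[c].append(i)
        return out


def modularity(
    graph: WeightedGraph, assignment: tuple[int, ...], resolution: float = 1.0
) -> float:
    """Weighted modularity Q of a partition, on absolute weights."""
    if len(assignment) != graph.n_nodes:
        raise ValueError("assignment must cover every node")
    a = np.abs(graph.weight_matrix())
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("graph has zero total weight")
    k = a.sum(axis=1)
    c = np.asarray(assignment)
    same = c[:, None] == c[None, :]
    return float(((a - resolution * np.outer(k, k) / two_m) * same).sum() / two_m)


def _local_phase(
    adj: list[dict[int, float]],
    loops: list[float],
    rng: np.random.Generator,
    resolution: float,
) -> list[int]:
    """One Louvain local-move phase on a weighted graph with self-loops.

    Nodes are visited in a freshly shuffled order each sweep; a node
    takes the first candidate community (neighboring communities plus
    one empty community, in shuffled order) with strictly positive
    modularity gain. Sweeps repeat until no node moves. First-improvement
    with shuffled candidate order explores more local optima across
    restarts than the deterministic best-gain rule.
    """
    n = len(adj)
    k = [sum(adj[i].values()) + 2.0 * loops[i] for i in range(n)]
    two_m = sum(k)
    comm = list(range(n))
    sigma_tot = k.copy()  # total degree per community
    size = [1] * n

    order = np.arange(n)
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for i in order:
            ci = comm[i]
            # weight from i to each neighboring community
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            sigma_tot[ci] -= k[i]
            size[ci] -= 1
            base = links.get(ci, 0.0) - resolution * sigma_tot[ci] * k[i] / two_m
            # candidates: neighbor communities plus one empty community
            # (leaving for a singleton is the only way out of a bad merge)
            candidates = sorted(links)
            empty = next((c for c in range(n) if size[c] == 0), None)
            if empty is not None and empty not in links:
                candidates.append(empty)
            rng.shuffle(candidates)
            chosen = ci
            for c in candidates:
                gain = (
                    links.get(c, 0.0)
                    - resolution * sigma_tot[c] * k[i] / two_m
                ) - base
                if gain > _GAIN_EPS:
                    chosen = c
                    break
            sigma_tot[chosen] += k[i]
            size[chosen] += 1
            if chosen != ci:
                comm[i] = chosen
                improved = True
    return comm


def _aggregate(
    adj: list[dict[int, float]],
    loops: list[float],
    comm: list[int],
) -> tuple[list[dict[int, float]], list[float], dict[int, int]]:
    """Collapse communities into super-nodes, summing edge weights."""
    ids = sorted(set(comm))
    remap = {c: i for i, c in enumerate(ids)}
    n_new = len(ids)
    new_adj: list[dict[int, float]] = [{} for _ in range(n_new)]
    new_loops = [0.0] * n_new
    for c, w in zip(comm, loops):
        new_loops[remap[c]] += w
    for i in range(len(adj)):
        ci = remap[comm[i]]
        for j, w in adj[i].items():
            if j <= i:
                continue
            cj = remap[comm[j]]
            if ci == cj:
                new_loops[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, new_loops, remap


def louvain(
    graph: WeightedGraph,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 16,
) -> CommunityPartition:
    """Two-phase Louvain community detection on absolute weights.

    Local moves (seeded shuffle, strictly positive gain) alternate with
    aggregation until modularity stops increasing. Because a single
    greedy pass can land in an order-dependent local optimum, the
    procedure runs ``restarts`` passes on substreams of ``seed`` and
    keeps the best-modularity partition. Final community ids are
    relabeled by descending size (ties by smallest member index), so
    identical seeds give identical output.
    """
    if graph.n_edges == 0:
        raise ValueError("community detection needs at least one edge")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: CommunityPartition | None = None
    for child in np.random.SeedSequence(seed).spawn(restarts):
        part = _louvain_once(graph, np.random.default_rng(child), resolution)
        if best is None or part.modularity > best.modularity + _GAIN_EPS:
            best = part
    return best


def _louvain_once(
    graph: WeightedGraph, rng: np.random.Generator, resolution: float
) -> CommunityPartition:
    n = graph.n_nodes
    adj: list[dict[int, float]] = [{} for _ in range(n)]
    for (i, j), (w, _) in graph.edges.items():
        aw = abs(w)
        adj[i][j] = adj[i].get(j, 0.0) + aw
        adj[j][i] = adj[j].get(i, 0.0) + aw
    loops = [0.0] * n

    node_to_comm = list(range(n))  # flat assignment on original nodes
    q_prev = modularity(graph, tuple(node_to_comm), resolution)
    while True:
        comm = _local_phase(adj, loops, rng, resolution)
        flat = [comm[node_to_comm[i]] for i in range(n)]
        # relabel contiguous for Q evaluation
        remap_flat = {c: i for i, c in enumerate(sorted(set(flat)))}
        flat = [remap_flat[c] for c in flat]
        q = modularity(graph, tuple(flat), resolution)
        if q <= q_prev + _GAIN_EPS:
            break
        q_prev = q
        adj, loops, remap = _aggregate(adj, loops, comm)
        node_to_comm = [remap[comm[node_to_comm[i]]] for i in range(n)]

    flat = [node_to_comm[i] for i in range(n)]
    # relabel by descending community size, ties by smallest member index
    sizes: dict[int, list[int]] = {}
    for i, c in enumerate(flat):
        sizes.setdefault(c, []).append(i)
    order = sorted(sizes, key=lambda c: (-len(sizes[c]), min(sizes[c])))
    relabel = {c: i for i, c in enumerate(order)}
    final = tuple(relabel[c] for c in flat)
    return CommunityPartition(assignment=final, modularity=q_prev)


def community_summary(
    partition: CommunityPartition, schema: VariableSchema
) -> list[list[str]]:
    """Communities as lists of variable labels, ordered by size then
    schema order (within and across communities)."""
    groups = partition.members()
    groups.sort(key=lambda g: (-len(g), g[0]))
    return [[schema.labels[i] for i in sorted(g)] for g in groups]
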