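"""Serialization of graphs (GEXF/GraphML) and analysis reports (JSON).

Graph files are written so that standard network software can read them:
node attributes (label, dimension, centralities, community id) and signed
edge weights are preserved, and re-reading a file reconstructs a graph
identical to the one written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .community import CommunityPartition
from .metrics import ActivationView, to_networkx
from .pcorr import WeightedGraph

GRAPH_FORMATS = ("gexf", "graphml")


def write_graph(graph: WeightedGraph, path: str | Path, format: str = "gexf") -> None:
    """Write a graph as GEXF 1.2 or GraphML; signed weights preserved."""
    if graph.n_nodes < 1:
        raise ValueError("graph must have at least one node")
    fmt = format.lower()
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown format {format!r}; use one of {GRAPH_FORMATS}")
    g = to_networkx(graph)
    if fmt == "gexf":
        nx.write_gexf(g, path, version="1.2draft")
    else:
        nx.write_graphml(g, path)


def read_graph(path: str | Path, format: str | None = None) -> WeightedGraph:
    """Read a graph written by :func:`write_graph` back into a
    :class:`WeightedGraph`; node order follows the file."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; use one of {GRAPH_FORMATS}")
    g = nx.read_gexf(path) if fmt == "gexf" else nx.read_graphml(path)
    nodes = tuple(g.nodes())
    index = {name: i for i, name in enumerate(nodes)}
    meta = tuple(
        {k: v for k, v in g.nodes[name].items() if k != "label"}
        | ({"label": g.nodes[name]["label"]} if "label" in g.nodes[name] else {})
        for name in nodes
    )
    edges = {}
    for u, v, attrs in g.edges(data=True):
        i, j = sorted((index[u], index[v]))
        edges[(i, j)] = (
            float(attrs["weight"]),
            float(attrs["p_value"]) if "p_value" in attrs else None,
        )
    return WeightedGraph(nodes, edges, node_meta=meta if any(meta) else None)


@dataclass(frozen=True)
class NetworkReport:
    """Per-stratum analysis bundle: graph, global metrics, centrality,
    communities and activation views."""

    stratum_label: str
    n: int
    graph: WeightedGraph
    global_metrics: dict  # edge_count, density, avg_path_length, diameter
    centrality: dict[str, dict[str, float]]
    communities: CommunityPartition
    community_labels: list[list[str]] = field(default_factory=list)
    most_relevant_node: str | None = None  # top eigenvector centrality
    bridging_node: str | None = None  # top closeness centrality
    activation: dict | None = None

    def to_dict(self) -> dict:
        return {
            "stratum_label": self.stratum_label,
            "n": self.n,
            "nodes": list(self.graph.nodes),
            "edges": [
                {"source": self.graph.nodes[i], "target": self.graph.nodes[j],
                 "weight": w, "p_value": p}
                for (i, j), (w, p) in sorted(self.graph.edges.items())
            ],
            "global_metrics": dict(self.global_metrics),
            "centrality": {k: dict(v) for k, v in self.centrality.items()},
            "communities": {
                "assignment": list(self.communities.assignment),
                "n_communities": self.communities.n_communities,
                "modularity": self.communities.modularity,
                "members": self.community_labels,
            },
            "most_relevant_node": self.most_relevant_node,
            "bridging_node": self.bridging_node,
            "activation": self.activation,
        }

    @staticmethod
    def from_dict(d: dict) -> "NetworkReport":
        nodes = tuple(d["nodes"])
        index = {n: i for i, n in enumerate(nodes)}
        edges = {}
        for e in d["edges"]:
            i, j = sorted((index[e["source"]], index[e["target"]]))
            edges[(i, j)] = (e["weight"], e["p_value"])
        return NetworkReport(
            stratum_label=d["stratum_label"],
            n=d["n"],
            graph=WeightedGraph(nodes, edges),
            global_metrics=d["global_metrics"],
            centrality=d["centrality"],
            communities=CommunityPartition(
                assignment=tuple(d["communities"]["assignment"]),
                modularity=d["communities"]["modularity"],
            ),
            community_labels=d["communities"]["members"],
            most_relevant_node=d["most_relevant_node"],
            bridging_node=d["bridging_node"],
            activation=d["activation"],
        )


def activation_to_dict(view: ActivationView) -> dict:
    return {
        "node": view.node,
        "activated": [{"node": n, "weight": w} for n, w in view.activated],
        "deactivated": list(view.deactivated),
    }


def write_report(
    reports: NetworkReport | list[NetworkReport], path: str | Path
) -> None:
    """Write one report (JSON object) or several (JSON array).

    Key order is construction order; floats use Python repr, which keeps
    full precision, so a read-back reproduces every metric bit-for-bit.
    """
    if isinstance(reports, NetworkReport):
        payload = reports.to_dict()
    else:
        payload = [r.to_dict() for r in reports]
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=False))


def read_report(path: str | Path) -> NetworkReport | list[NetworkReport]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        return [NetworkReport.from_dict(d) for d in data]
    return NetworkReport.from_dict(data)
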