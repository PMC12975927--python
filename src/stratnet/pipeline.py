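"""End-to-end stratified network analysis.

One call runs the whole battery the way the clinical analysis is
structured: load (or simulate) the cohort, run the descriptive
group-comparison table, split by stratum, and for each stratum estimate
the significance-sparsified partial-correlation network, compute global
metrics, centralities, communities and the activation view of the
bridging node. Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import community as community_mod
from . import metrics as metrics_mod
from .cohort import CohortTable, load_cohort, split_by_stratum
from .groupstats import table_one
from .pcorr import DEFAULT_ALPHA, WeightedGraph, estimate_stratum_network
from .report import NetworkReport, activation_to_dict, write_graph, write_report

logger = logging.getLogger("stratnet")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full analysis run."""

    input_path: str | None = None  # cohort CSV; None -> simulate
    design_path: str | None = None  # simulation design JSON (optional)
    stratum_column: str = "FA"
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    resolution: float = 1.0
    listwise_deletion: bool = False
    output_dir: str | None = None
    graph_format: str = "gexf"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.graph_format not in ("gexf", "graphml"):
            raise ValueError(f"unknown graph format {self.graph_format!r}")

    @staticmethod
    def from_json_file(path: str | Path, **overrides) -> "PipelineConfig":
        base = json.loads(Path(path).read_text())
        base.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**base)


def _pick_top(scores: dict[str, float], tiebreak: dict[str, float],
              order: tuple[str, ...]) -> str:
    """Argmax with ties broken by a secondary score, then node order."""
    rank = {name: i for i, name in enumerate(order)}
    return max(
        scores,
        key=lambda n: (scores[n], tiebreak.get(n, 0.0), -rank[n]),
    )


def analyze_stratum(
    cohort: CohortTable,
    label: str,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    resolution: float = 1.0,
) -> NetworkReport:
    """Estimate one stratum's network and its complete metric bundle.

    The report names the top-eigenvector node (the network's "most
    relevant" variable) and the top-closeness node (the "bridging" node,
    ties broken by eigenvector centrality, then schema order), and
    carries the bridging node's activation view.
    """
    graph = estimate_stratum_network(cohort, alpha)
    n_nodes = graph.n_nodes
    edge_count = graph.n_edges
    dens = metrics_mod.density(graph)
    if edge_count > 0:
        apl, diam = metrics_mod.shortest_path_stats(graph)
        cent = metrics_mod.centrality_table(graph)
        part = community_mod.louvain(graph, seed=seed, resolution=resolution)
        labels = community_mod.community_summary(part, cohort.schema)
        eig = {n: c["eigenvector"] for n, c in cent.items()}
        clo = {n: c["closeness"] for n, c in cent.items()}
        most_relevant = _pick_top(eig, clo, graph.nodes)
        bridging = _pick_top(clo, eig, graph.nodes)
        activation = activation_to_dict(
            metrics_mod.activation_view(graph, bridging)
        )
    else:  # degenerate but legal: nothing survived the threshold
        apl, diam = float("nan"), 0
        cent = {}
        part = community_mod.CommunityPartition(
            assignment=tuple(range(n_nodes)), modularity=0.0
        )
        labels = community_mod.community_summary(part, cohort.schema)
        most_relevant = bridging = None
        activation = None

    # attach metrics to node metadata for graph serialization
    meta = []
    for i, name in enumerate(graph.nodes):
        m = dict(graph.node_meta[i]) if graph.node_meta else {}
        if name in cent:
            m["eigenvector"] = cent[name]["eigenvector"]
            m["closeness"] = cent[name]["closeness"]
            m["clustering"] = cent[name]["clustering"]
        m["community"] = int(part.assignment[i])
        meta.append(m)
    graph = WeightedGraph(graph.nodes, graph.edges, node_meta=tuple(meta))

    return NetworkReport(
        stratum_label=label,
        n=cohort.n,
        graph=graph,
        global_metrics={
            "edge_count": edge_count,
            "density": dens,
            "avg_path_length": apl,
            "diameter": diam,
        },
        centrality=cent,
        communities=part,
        community_labels=labels,
        most_relevant_node=most_relevant,
        bridging_node=bridging,
        activation=activation,
    )


def run_stratified_analysis(
    config: PipelineConfig, cohort: CohortTable | None = None
) -> tuple[NetworkReport, NetworkReport, dict]:
    """Full pipeline: (positive-stratum report, negative-stratum report,
    comparison table). Writes graph and JSON outputs when
    ``config.output_dir`` is set; partial outputs are removed on error."""
    t0 = time.perf_counter()
    if cohort is None:
        if config.input_path is not None:
            cohort = load_cohort(
                config.input_path,
                stratum_column=config.stratum_column,
                allow_listwise_deletion=config.listwise_deletion,
            )
        else:
            from .simulate import SimulationDesign, default_design, generate_cohort

            design = (
                SimulationDesign.from_json_file(config.design_path)
                if config.design_path
                else default_design(seed=config.seed)
            )
            cohort = generate_cohort(design, seed=config.seed)
    logger.info(
        "stage=load n=%d variables=%d elapsed=%.3fs",
        cohort.n, len(cohort.schema), time.perf_counter() - t0,
    )

    written: list[Path] = []
    try:
        stage = "table_one"
        comparison = table_one(cohort)
        stage = "split"
        pos, neg = split_by_stratum(cohort)
        stage = "network:positive"
        report_pos = analyze_stratum(
            pos, "FA+", config.alpha, config.seed, config.resolution
        )
        stage = "network:negative"
        report_neg = analyze_stratum(
            neg, "FA-", config.alpha, config.seed, config.resolution
        )
        if config.output_dir is not None:
            stage = "write"
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            for rep, tag in ((report_pos, "fa_plus"), (report_neg, "fa_minus")):
                gpath = out / f"network_{tag}.{config.graph_format}"
                write_graph(rep.graph, gpath, config.graph_format)
                written.append(gpath)
                epath = out / f"edges_{tag}.csv"
                _write_edge_list(rep.graph, epath)
                written.append(epath)
            rpath = out / "report.json"
            write_report([report_pos, report_neg], rpath)
            written.append(rpath)
            cpath = out / "comparisons.json"
            cpath.write_text(json.dumps(_comparison_payload(comparison), indent=2))
            written.append(cpath)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    logger.info(
        "stage=done seed=%d alpha=%.3f elapsed=%.3fs",
        config.seed, config.alpha, time.perf_counter() - t0,
    )
    return report_pos, report_neg, comparison


def _write_edge_list(graph: WeightedGraph, path: Path) -> None:
    lines = ["source,target,weight,p_value"]
    for (i, j), (w, p) in sorted(graph.edges.items()):
        lines.append(f"{graph.nodes[i]},{graph.nodes[j]},{w!r},{p!r}")
    path.write_text("\n".join(lines) + "\n")


def _comparison_payload(comparison: dict) -> dict:
    return {
        "n": comparison["n"],
        "descriptives": comparison["descriptives"],
        "comparisons": [asdict(c) for c in comparison["comparisons"]],
    }
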