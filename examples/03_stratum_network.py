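"""Estimate one stratum's partial-correlation network.

Edge weights are partial correlations (each pair conditioned on the
other 15 variables); only edges with p < 0.25 are retained — a
deliberately liberal rule that favors sensitivity over specificity.
"""

import stratnet as sn

cohort = sn.generate_cohort(sn.default_design(seed=7))
pos, _ = sn.split_by_stratum(cohort)

threshold = sn.edge_p_threshold(pos.n, k=15, alpha=0.25)
print(f"FA+ stratum: n={pos.n}; p<0.25 keeps |r| > {threshold:.3f}")

graph = sn.estimate_stratum_network(pos, alpha=0.25)
print(f"retained {graph.n_edges} of 136 potential edges "
      f"(density {sn.density(graph):.3f})")

apl, diam = sn.shortest_path_stats(graph)
print(f"average path length {apl:.3f} hops, diameter {diam}")

strongest = sorted(graph.edges.items(), key=lambda e: -abs(e[1][0]))[:5]
print("strongest edges (signed partial correlation):")
for (i, j), (w, p) in strongest:
    print(f"  {graph.nodes[i]:<20} -- {graph.nodes[j]:<20} r={w:+.3f} p={p:.4f}")
# Negative weights are real features: they are conditional associations
# that reverse sign once the other 15 variables are controlled.
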