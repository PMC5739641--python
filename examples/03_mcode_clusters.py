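"""Detect dense miRNA complexes with MCODE and score their densities.

Three 8-member modules at Spearman 0.9 are planted among 200 background
miRNAs. Edges are gated at BH-corrected p < 0.05 (at ~20k pairwise tests
raw-p gating would flood the graph with false edges). Each detected
cluster is printed with its density and the binomial-null p-value of that
density given the global edge probability.
"""

from mirnet import (SimulationConfig, ModuleSpec, simulate_study,
                    spearman_matrix, build_network, mcode_clusters,
                    cluster_density_pvalue)

cfg = SimulationConfig(n_pairs=50, n_features=224,
                       modules=tuple(ModuleSpec(8, 0.9) for _ in range(3)),
                       seed=11)
study, truth = simulate_study(cfg)
net = build_network(spearman_matrix(study, tissue="tumour"),
                    alpha=0.05, bh_correct=True)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges")

clusters = mcode_clusters(net)
print(f"MCODE found {len(clusters)} cluster(s):")
for i, c in enumerate(clusters, 1):
    p = cluster_density_pvalue(c, net)
    best = max((len(truth.module_members(m) & c.members)
                / len(truth.module_members(m) | c.members)
                for m in truth.module_ids), default=0)
    print(f"  cluster {i}: {c.size} miRNAs, seed {c.seed}, "
          f"density {c.density:.3f}, p={p:.2e}, "
          f"best Jaccard vs planted modules {best:.2f}")
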