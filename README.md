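# mirnet

Co-expression network analysis for small paired miRNA expression studies.

Tumour profiling studies with matched normal/tumour tissue pairs — often
with fewer than ten subjects per cohort — need more than per-miRNA fold
changes: the interesting biology sits in how miRNAs *co-vary*, and how
that correlation structure reorganises between normal and tumour tissue.
`mirnet` implements that analysis end to end for researchers working with
processed (log2, normalised) expression matrices:

1. **Paired differential expression** — per-miRNA paired t-test on
   within-subject log2 differences d_i = x_i,tumour − x_i,normal
   (t = d̄·√n/s_d, df = n−1), Benjamini–Hochberg q-values, and the
   sign-encoded linear fold-change convention of microarray tables
   (−1.5 ⇒ 1.5-fold down; no value in (−1, 1)).
2. **Correlation networks** — undirected graphs whose edges are miRNA
   pairs with significant Spearman ρ within a sample stratum; edges carry
   ρ (weight), p and a direct/inverse sign. In strata of ≤ 9 samples the
   p-value comes from the exact permutation null rather than the
   t-approximation.
3. **Topology** — global geometric attributes (components, diameter,
   characteristic path length, Freeman degree centralization
   (N/(N−2))·(k_max/(N−1) − density), density 2E/N(N−1), mean neighbour
   count 2E/N, degree heterogeneity sd(k)/mean(k)) and local centralities
   (degree, betweenness, closeness, clustering and topological
   coefficients, per-node mean shortest path) where path length is the
   sum of inverse edge weights 1/|ρ|.
4. **MCODE clustering** — vertex weighting by the highest k-core of each
   closed neighbourhood (score = k·density), seeded complex growth,
   haircut/fluff post-processing, plus a binomial-null p-value for each
   cluster's density (with a degree-preserving rewiring null as a
   cross-check).
5. **Network comparison** — shared/specific nodes and edges between
   conditions, edge preservation and sign concordance against an
   independent dataset's correlation table, motif census
   (pairs/triangles/chains) and per-miRNA neighbourhood extraction.
6. **Target enrichment** — miRNA → validated-target mapping and
   hypergeometric over-representation against GMT gene sets with
   Bonferroni control.

A first-class synthetic-data generator produces paired studies with
planted differential expression and planted correlation modules, so every
stage can be validated against known ground truth.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/03_mcode_clusters.py` simulates 50 matched pairs with
three planted 8-miRNA modules (target Spearman 0.9) among ~200
background miRNAs, wires the tumour-stratum network at BH-corrected
p < 0.05, and clusters it:

```
network: 224 nodes, 87 edges
MCODE found 3 cluster(s):
  cluster 1: 8 miRNAs, seed sim-miR-0005, density 1.000, p=1.50e-69, best Jaccard vs planted modules 1.00
  cluster 2: 8 miRNAs, seed sim-miR-0019, density 1.000, p=1.50e-69, best Jaccard vs planted modules 1.00
  cluster 3: 8 miRNAs, seed sim-miR-0070, density 1.000, p=1.50e-69, best Jaccard vs planted modules 1.00
```

All three planted modules come back as perfect-density complexes
(Jaccard 1.0 against ground truth); the binomial p-value says a
28-edge-complete subgraph of 8 nodes is vanishingly unlikely at the
network's global edge probability. `examples/01_simulate_and_diffexpr.py`
shows the differential-expression side: with 9 pairs and noise SD 0.3 all
10 planted miRNAs with |log2FC| ≥ 1 are recovered at p < 0.05, alongside
the ~5% of background features expected by chance.

The same analysis runs from a shell via the thin CLI
(`mirnet simulate | diffexpr | network | topology | mcode | compare |
enrich | run-all`); `mirnet run-all config.yaml` executes the whole
pipeline from one YAML config and writes TSV/GraphML outputs with a JSON
manifest (rerunning a config is byte-identical).

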