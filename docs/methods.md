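# Methods

## Study design and data model

The package analyses paired two-tissue expression studies: each subject
contributes one normal and one tumour sample, and values are log2
intensities assumed already normalised — no normalisation is ever
applied. An `ExpressionStudy` holds a feature × sample matrix plus a
sample sheet (sample id, subject id, tissue, cohort); validation enforces
unique ids, exactly one normal and one tumour sample per subject, and
drops features containing missing values with a warning (a policy choice;
array-processing pipelines differ and the package takes the conservative
route of never imputing).

Gene symbols in target maps and GMT collections are upper-cased on load
so joins are case-insensitive. Alias application is functional
(one current symbol per legacy symbol); when two legacy probes collapse
onto one current symbol the higher-mean-intensity feature survives, on
the rationale that the brighter probe carries more signal.

## Synthetic data generator

The generator is the package's ground-truth instrument. On the log2
scale, the value of feature i in sample (subject j, tissue t) is

    x_ijt = mu_i + s_ij + delta_i·[t = tumour] + a_i·z_(m(i), jt) + e_ijt

* `mu_i` — baseline, uniform on `baseline_mean_range` (default 6–12,
  typical of log2 array intensities).
* `s_ij` — a per-(feature, subject) random effect, N(0, subject_sd),
  added to *both* tissues of the pair. This induces the within-pair
  correlation a paired design exploits while leaving distinct features
  independent; default subject_sd = noise_sd.
* `delta_i` — planted differential expression: for `n_de` randomly chosen
  features, a random sign times a uniform draw from `de_log2fc_range`.
  The tumour−normal difference d_ij = delta_i + a_i(z_T − z_N) + (e_T −
  e_N) has mean delta_i exactly, and the subject effect cancels, so the
  paired t-test is exactly calibrated on background features.
* `z_(m, jt)` — one standard-normal latent factor per module per sample.
  Module members load with a_i = ±a where a² = ρ·(subject_sd² +
  noise_sd²)/(1 − ρ), which makes the within-stratum Pearson correlation
  of two same-sign members exactly `rho_target`; Spearman ≈ Pearson under
  Gaussianity (the classical 6/π·asin(ρ/2) relation differs from ρ by
  < 0.02 over the usable range), which is accepted and tested empirically.
  `sign_pattern="inverse"` alternates loading signs (with more than two
  members not every pair can be negatively correlated — a mathematical
  constraint of any one-factor construction, not an implementation
  limit); `"mixed"` draws signs at random.
* `e_ijt` — i.i.d. N(0, noise_sd), default 0.3 on the log2 scale.

Defaults (9 pairs, ~1105 features) mirror a small matched-pair microarray
cohort. Everything is drawn from one `numpy` generator seeded by
`config.seed`, so identical configs are bit-identical.

What the generator does **not** emulate: probe-level effects, batch and
array-quality artefacts, heavy-tailed or intensity-dependent noise,
correlated background features, and missingness. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
Gaussian paired design, not robustness to real-array pathologies.

## Differential expression

Per feature, a paired t-test on within-subject log2 differences
(df = n_pairs − 1, two-sided). Zero-variance difference vectors leave t
undefined; such features are reported with p = 1 and a warning rather
than dropped. Benjamini–Hochberg q-values are computed over all tested
features, but **selection gates on raw p < 0.05 by default** — the
convention of the fold-change tables this mirrors, where many reported
miRNAs sit between p 0.01 and 0.05 — with `use_q=True` exposing the
stricter gate. The signed fold-change encodes m = mean log2 difference as
2^m for m ≥ 0 and −2^(−m) otherwise; the encoding is bijective and
round-trips.

The cross-cohort contrast applies a Welch two-sample t-test to the
subject-level paired differences of two cohorts. Welch rather than pooled
variance because the intended use case is small, unequal cohorts
(e.g. 9 vs 4 pairs), where the equal-variance assumption buys nothing.

## Correlation networks

Spearman ρ with midranks, computed per sample stratum (tissue and/or
cohort). Significance:

* strata with > 9 samples: the usual two-sided t-approximation
  t = ρ√((n−2)/(1−ρ²));
* strata with ≤ 9 samples: an **exact permutation p-value**. With
  tie-free ranks the null distribution of ρ depends only on n and is
  tabulated once per n over all n! permutations; with ties the
  permutation distribution is computed for the pair's actual midranks.
  The t-approximation is materially anticonservative at n = 4–6, which
  is exactly the regime of a four-pair cohort, hence the switch.

Edges join pairs with p < alpha (default 0.05, no multiple-testing
correction — matching the analysis convention this reproduces). A
`bh_correct` flag applies Benjamini–Hochberg across the pair p-values
instead; this is the recommended setting when the feature subset is
large (hundreds of miRNAs mean 10⁴–10⁵ pair tests, and at raw 0.05 the
false edges dominate and chain otherwise-separate dense regions
together). Thresholding is on p only, not on |ρ|. Constant features get
ρ = 0, p = 1 with a warning. The node set is the full supplied subset, so
unconnected miRNAs stay visible as isolated nodes.

## Topology

Two deliberate distance conventions coexist:

* **Global** attributes (component count, diameter, characteristic path
  length, ordered reachable-pair count and its fraction of N(N−1)) are
  computed on the unweighted graph — these mirror the attribute panel of
  standard network viewers. Centralization is Freeman degree
  centralization (N/(N−2))·(k_max/(N−1) − density) (1 for a star, 0 for
  any regular graph; defined as 0 at N = 2), heterogeneity is
  sd(k)/mean(k) with population variance. Disconnected graphs use the
  largest component for the diameter and reachable pairs only for the
  characteristic path length.
* **Local** centralities use edge length 1/|ρ|: strongly correlated
  miRNAs are close, and the sign is ignored because a strong inverse
  correlation is as informative a link as a direct one. Betweenness is
  normalised by the non-involved ordered pair count (so the middle of a
  3-node path scores 1.0); closeness uses the Wasserman–Faust form,
  which stays in [0, 1] on disconnected graphs and reduces to classical
  closeness on connected ones; the clustering coefficient is unweighted;
  the topological coefficient of v averages (shared neighbours + 1 if
  adjacent)/k(v) over all nodes sharing at least one neighbour with v.
  Isolated nodes get zeros and an `asp_defined=False` flag instead of an
  undefined mean distance.

Top-k ranking per index sorts descending (ties by id) and includes
boundary-tied nodes beyond rank k with an explicit flag, so tie-breaking
never silently drops a node.

## MCODE

Faithful to the published three-phase algorithm on the unweighted
topology (correlation weights do not enter scoring): vertex score =
k × density of the highest k-core of the closed neighbourhood (0 below
the degree cutoff); growth from the highest-scoring unassigned seed
admits neighbours with score ≥ seed_score·(1 − node_score_cutoff) breadth
first up to `max_depth`; haircut restricts a complex to the 2-core of its
induced subgraph — i.e. singly-connected members are removed *to a fixed
point*, which makes the operation idempotent (a single removal pass is
not, since removals create new degree-1 nodes); fluff optionally adds
neighbour shells above a density cutoff and is the only way complexes may
overlap. Defaults are the published ones: degree cutoff 2, node score
cutoff 0.2, haircut on, fluff off. Ties at equal seed score break
lexicographically, so output is deterministic.

One behavioural consequence worth knowing: two dense regions joined by a
single edge between two high-scoring members are traversed by growth and
merge into one complex (haircut does not split them, as both endpoints
keep degree ≥ 2). This is inherent to the score-threshold growth rule;
on large noisy networks the practical remedy is stricter edge gating
(see `bh_correct` above), not a modified algorithm.

Cluster density significance: the default analytic null treats each of
the C(k,2) member pairs as an independent edge with probability equal to
the global density and takes the binomial upper tail at the observed
edge count. It is a convenient, slightly liberal null (it ignores the
degree sequence and the selection effect of clustering); a
degree-preserving double-edge-swap permutation null is available as a
cross-check and is the honest choice when the degree distribution is
extreme. Printed cluster p-values from other toolchains are not
comparable across null choices.

## Network comparison

Edge identity across networks is the unordered miRNA-id pair; weights are
irrelevant to identity. "No shared links" nodes are present in both
networks, incident to at least one edge, with disjoint incident edge
sets (isolated-in-both nodes are in neither category); "all links shared"
requires exact coincidence. Preservation against a reference dataset
*recomputes* significance in the reference correlation table at the same
alpha — it does not intersect published edge lists — and concordance
additionally requires matching ρ sign; pairs outside the reference
feature space count as unpreserved and are reported separately.

The motif census classifies components as isolated node, pair, triangle,
chain (induced path: two degree-1 ends, all internal degrees 2 — trees
that are not paths fall into "other"), or other; class counts always sum
to the component count. Triangles are enumerated by ordered adjacency
intersection over the whole graph, not only triangle components. The
longest chain is returned with its edge-sign sequence so runs of
consecutive inverse correlations can be counted.

## Enrichment

Hypergeometric upper tail per gene set, Bonferroni across the sets
tested, significance flag at corrected p ≤ 0.05. The universe defaults to
the union of the collection's member genes: the effective universes of
hosted enrichment services are irreproducible, so the package makes the
universe explicit and overridable instead. The packaged pathway GMT and
target map are small illustrative (synthetic) stand-ins for curated
databases — enough to demonstrate the interface offline, with no claim of
database fidelity.

## Pipeline

Per cohort: differential expression → per-tissue networks over the
deregulated set (both strata) → topology reports → MCODE with density
p-values on the configured stratum's network (tumour by default — when a
single "disease-altered" network is wanted the tumour stratum is the
natural default, and the choice is exposed as `network_stratum`) →
comparison + census → enrichment; with ≥ 2 cohorts, a Welch contrast on
paired differences. Outputs are TSV/GraphML with stable names plus a
manifest (config hash, seed, version); reruns of the same config are
byte-identical. The CLI is a thin wrapper over these functions.

## Problem sizes and numerical choices

Simulation-based checks in the test suite use: type-I error averaged
over 10 replicate 1000-feature null studies of 9 pairs (binomial SE
≈ 0.002 at 10⁴ tests, making the ±0.01 calibration band meaningful);
recovery runs at 50 pairs, 550 features, three planted 8-member modules
at ρ 0.9, noise SD 0.3; oracle-equivalence sweeps use ≥ 200 random
graphs of ≤ 8 nodes against exhaustive path/subset enumeration. Exact
permutation Spearman p-values cache the tie-free null per stratum size
(≤ 9! = 362 880 permutations). Floating-point comparisons in shortest-
path oracles use a 1e-9 tolerance on path weights. Degenerate inputs are
defined, not crashed: zero-variance t-tests report p = 1, constant
correlation features get ρ = 0/p = 1, isolated nodes carry zero
centralities with an explicit flag, and empty graphs yield empty cluster
lists.

## Known limitations

* Correlation networks on 4–9 pairs are severely power-limited; the
  exact permutation p floors at 2/n!, so at n = 4 no edge can pass
  alpha = 0.05 two-sided unless ρ = ±1 (p = 2/24 ≈ 0.083 even then) —
  small-cohort networks should be read descriptively.
* The binomial cluster-density null ignores degree structure and
  selection; use the permutation null for strong claims.
* No partial correlations or graphical models: edges are marginal
  associations and shared latent drivers produce cliques, not hubs.
* The generator's Gaussian, homoscedastic noise understates real-array
  tail behaviour; planted-recovery rates are upper bounds on field
  performance.
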