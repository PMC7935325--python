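# Methods

This note documents the models, statistics and numerical conventions behind
`sepsisnet`, the design choices made where conventions genuinely diverge,
and what the synthetic-data validation does and does not establish about
real transcriptome data.

## Scope and data model

The package operates on already-summarized expression matrices: genes ×
samples, log2 scale, with each sample labeled `control` or `case` and
optionally `survivor` / `nonsurvivor`. Platform-level processing (CEL
parsing, RMA summarization, bead-level handling) is out of scope; the
normalization operations provided are the two that act on a summarized
matrix — elementwise log2 and quantile normalization. Quantile
normalization assigns every column the mean-of-sorted-columns reference
distribution by within-column rank; tied input values receive the mean of
their tied positions' reference values. On tie-free columns the operation
is idempotent to machine precision (tie-averaging can alter a column's
value multiset, so with ties idempotence holds only approximately — the
same behavior as the standard implementations).

Missing values: genes containing any missing entry are dropped at ingestion
(with a logged count). Correlation and t statistics need complete per-gene
vectors, and imputation would manufacture correlation structure — the one
thing this pipeline must not do.

Probe collapsing keeps, per gene, the probe with maximal mean expression
(ties broken by lexicographic probe ID). This is a declared convention, not
a community-unique truth; max-mean is the common default and is
deterministic.

Balanced subsampling draws exactly `n_control` cases without replacement
from a single `numpy` generator keyed by the user's seed, so the selection
— unlike an unlogged manual randomization — is reproducible from the run
manifest.

## Annotation: majority vote with tie demotion

The shipped registry maps the 21 KEGG immune-system pathways onto 10
functional categories. Each gene's category is the mode of its pathway
memberships across all loaded sources (KEGG, GO, Reactome — all votes
weigh equally; a gene in three adaptive-immunity pathways casts three
adaptive votes). Ties are resolved in two steps: if the tied categories mix
members of the broad trio {cytokines-chemokines, signaling, hematopoiesis}
with more specific categories, the trio members are discarded and the vote
re-evaluated; if a single category survives it wins, otherwise the gene is
labeled `U` (undetermined). Ties entirely inside the trio, or among several
specific categories, are also `U` — the demotion clause gives no guidance
there, and refusing to guess is the conservative reading.

The shipped gene sets are reduced, representative member lists (a synthetic
stand-in, named accordingly), adequate for exercising and testing the
machinery; analyses of real data should load full GMT exports through
`load_registry`, which accepts any number of GMT files plus a
pathway→category map.

## Differential expression

Welch's unequal-variance t-test per gene, two-sided, with
Benjamini–Hochberg FDR control (via `statsmodels`, verified in the test
suite against a hand-written step-up oracle) and a default significance
cutoff of q < 0.01. Welch rather than pooled-variance is a deliberate
robustness choice and is stated here because "a t-test" underdetermines it.
Genes with zero variance and equal means in both groups receive t = 0,
p = 1 rather than NaN.

Under a simulated null (both groups N(0,1), n = 20/group, 1000 genes) the
empirical type-I error at α = 0.05 is verified to sit within 0.05 ± 0.02.

## Gene-set enrichment (GAGE-style)

The directional pathway test follows the generally-applicable
gene-set-enrichment scheme, re-implemented with one declared variant: the
"one-on-group-mean" comparison. For each case sample j, per-gene fold
changes f_ij = x_ij − mean_i(control). For each pathway, a two-sample
unequal-variance t statistic compares the pathway genes' fold changes to
the complement's, per case sample; one-sided p-values (on k−1 degrees of
freedom, k = pathway size in the matrix — a conservative choice) are
combined across case samples by Stouffer's method into a global p per
direction, flagged at global p < 0.05.

The Stouffer combination uses a correlation-corrected denominator. Because
every case sample's fold changes subtract the *same* control mean, the
per-sample set-vs-complement contrasts share that control-mean noise and
their z-scores are equicorrelated with ρ = 1/(n_ctrl + 1) (derived from the
variance decomposition of the contrast). The combined statistic is
therefore Σz / √(n_case + n_case(n_case−1)ρ). With the naive √n_case
denominator the null flagging rate roughly doubles at n = 20/20; with the
correction, simulation shows ~5–9 null sets flagged per 100 at α = 0.05
(both directions pooled) and 100/100 detection of a 30-gene set shifted by
+1 SD against 500 background genes.

Two caveats inherent to the scheme: the test is *relative* (set vs
complement), so when one large set moves, its complement is symmetrically
flagged in the opposite direction; and pathways overlapping the matrix by
fewer than 2 genes are skipped with a warning.

## Network construction

Spearman correlations are computed within one sample group as Pearson
correlations of midranks (average ranks for ties), requiring ≥ 4 samples.
Two-sided p-values use the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2
degrees of freedom; numerically perfect monotone pairs are snapped to
ρ = ±1 and assigned p = 0. Zero-variance genes have undefined correlations
(NaN) and are excluded from the graph, with a warning.

An edge joins genes i, j iff ρ_ij ≥ 0.8 (signed — this follows the usual
"equal to or greater than 0.8" convention; an `absolute=True` flag
thresholds |ρ| instead) and p < 0.05. No multiple-testing correction is
applied to edges: the raw p < 0.05 filter is part of the method being
reproduced and is preserved deliberately. Degree-0 genes are dropped, so
the node counts reported refer to connected genes only — a fraction of the
full panel. Networks are built separately per group (control vs case, or
survivor vs nonsurvivor via the outcome labels).

## Topology metrics

Conventions follow the Cytoscape NetworkAnalyzer tool, the de-facto
standard for these reports:

- **Clustering coefficient** C_n = 2e_n/(k_n(k_n−1)); the network value
  averages nodes with degree ≥ 2 (a flag includes degree-<2 nodes as 0).
- **Density** 2E/(N(N−1)); equals ⟨k⟩/(N−1) identically.
- **Heterogeneity** √var(k)/mean(k) — the coefficient of variation of the
  degree distribution (population variance). A plain variance/mean variant
  is exposed behind `heterogeneity_formula="variance"` because the two
  readings coexist in the literature; the CV form is the default since it
  is what NetworkAnalyzer computes.
- **Centralization** (N/(N−2))(k_max/(N−1) − density): 1 for a star, 0 for
  any regular graph, undefined (reported as missing) for N < 3.
- **Path metrics** (diameter, characteristic path length, shortest-path
  count) are taken over *connected ordered* node pairs only, so
  multi-component graphs yield finite values; the shortest-path count is
  the number of ordered connected pairs.
- **Degree correlation μ** is Newman's edge-wise Pearson degree
  assortativity (undefined on degree-regular graphs, reported as missing).
  A neighbor-connectivity regression is an alternative reading of "degree
  correlation"; assortativity is the default because it is the standard
  single-number summary.
- **Betweenness** is Brandes-accumulated and normalized by (N′−1)(N′−2)/2
  within each connected component of size N′ (0 for components smaller
  than 3). **Stress** is the raw count of geodesics through a node over
  unordered endpoint pairs, computed by a Brandes-style accumulation of
  path counts. **Closeness** is 1/mean distance to reachable nodes;
  **eccentricity** is the maximum distance within the component.
- **Topological coefficient** T_n = mean over partners m (nodes sharing at
  least one neighbor with n) of (|N(n)∩N(m)| + [m adjacent to n])/k_n.
- **Modularity** uses greedy agglomerative (CNM) modularity maximization —
  deterministic, so reruns agree bit-for-bit — and reports the
  Newman–Girvan Q of the resulting partition. A seed parameter exists for
  API stability with randomized refinements. Worked anchors: two disjoint
  triangles give Q = 0.5; any single community spanning a connected graph
  gives Q = 0.

Every metric is validated in the test suite against independent brute-force
oracles (exhaustive triangle enumeration, Floyd–Warshall distances, full
recursive geodesic enumeration) on 50 random graphs with N ≤ 40 — exactly
for counts, to 1e-9 for reals.

## Cross-condition comparison

Percent difference is (case − control)/control × 100, reported at full
precision with a one-decimal display rounding (round-half-even); control
values of 0, or parameters undefined on either side, yield a missing entry
rather than an error. The two anchor computations: clustering coefficients
(survivor 0.390, nonsurvivor 0.337) → −13.59% (displayed −13.6, reported
elsewhere as −13.5 under truncation-style rounding — the acceptance check
tolerates ±0.15 percentage points); modularities (0.581, 0.694) → +19.45%.

A *prominent isolated cluster* is operationalized as: a connected component
of size ≥ 5 (configurable) whose dominant category is enriched at one-sided
hypergeometric p < 0.05, flagged `is_isolated` when it is not the largest
component. The default enrichment background is the full annotated gene
panel rather than the network's own nodes: thresholded immune networks can
shrink to little more than one dense module, and a background restricted to
network nodes cannot call a component enriched when the component *is* the
network. The network-internal background remains available
(`background="network"`) for graphs embedded in a larger connected context.
No multiple-testing correction is applied across components (few
components, exploratory use).

Consensus across datasets tallies, per gene, the number of datasets whose
isolated clusters (of a chosen category) contain it, plus the intersection;
and, per pathway × direction, the number of datasets where enrichment is
significant — the "5/6 datasets" style summary.

## Synthetic data: what it emulates and what it does not

The generator produces genes × samples Gaussian matrices on a log2-like
intensity scale (baseline mean 8, SD 1 — typical of microarray log2
intensities) with three planted structures: equicorrelated gene blocks
(optionally group-specific), mean shifts in the case group, and independent
background noise. Blocks are sampled via the one-factor representation
x = √ρ·z_block + √(1−ρ)·ε, which realizes the equicorrelated covariance
exactly and guarantees positive semi-definiteness for ρ ∈ [0, 1); ρ ≥ 1 or
negative block correlations are rejected. For a group-specific block,
`rho_in` applies in the active group and `rho_out` (default 0, i.e.
independence) in the other group. For bivariate Gaussians the population
Spearman correlation is (6/π)·asin(ρ/2) — 0.892 at ρ = 0.9 — so
Spearman-threshold edge recovery targets sit slightly below the planted
Pearson value.

Default study conditions (`default_config`): 320 genes of which a 20-gene
adaptive-immunity block is case-active at ρ = 0.9, 30 genes shifted +1 SD
in cases, 25 samples per group — sample sizes and effect scales typical of
the whole-blood cohorts this workflow targets, and the configuration under
which the recovery rates below are quoted.

Deliberately not modeled: probe-level structure, count-based (RNA-seq)
noise, batch effects, heavy-tailed intensities, and correlated background
beyond the planted blocks. Consequently, passing recovery tests shows the
pipeline correctly extracts the structure it is designed to detect from
Gaussian data; it does not certify behavior under platform artifacts or
confounding, which real cohort analyses must assess separately.

Validated recovery under the default conditions (100 simulations each, in
the test suite and `scripts/acceptance.py`): the case-group network
isolates the planted block as a dominant-category enriched component in
100/100 runs; the control-group network produces no such finding in
100/100; a +1 SD 30-gene set is flagged up-regulated in 100/100; null sets
are flagged in ≤ 10/100.

## Determinism

All randomness flows through `numpy.random.default_rng` instances keyed by
explicit seeds; there is no global-state seeding. The pipeline writes a
manifest (package version, seed, thresholds, input description) sufficient
to reproduce the bundle, and a rerun with the same config and seed is
bit-identical — asserted file-by-file in the acceptance suite.

## Known limitations

- The edge filter uses raw per-pair p-values (by design, see above); at
  α = 0.05 and ~50k gene pairs, some spurious edges are expected in sparse
  regimes.
- Greedy modularity maximization is a heuristic; Q is a lower bound on the
  optimum, and its resolution limit can merge small true communities.
- The GAGE variant here is deterministic but not the original package's
  sampling scheme; absolute global p-values are comparable within this
  implementation, not across implementations.
- Annotation quality is bounded by the loaded gene sets; the shipped
  registry is a reduced stand-in, and category assignments on real data
  require full pathway exports.
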