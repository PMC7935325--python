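# sepsisnet

Immune gene co-expression network analysis for sepsis transcriptomes.

Sepsis is a dysregulated host response to infection, and its immune
signature is distributed across hundreds of interacting genes rather than a
handful of markers. `sepsisnet` analyzes that signature as a network: genes
from the immune-system pathways are annotated with functional categories,
per-group co-expression networks are built from rank correlations, and the
networks' topology is compared between conditions (control vs sepsis,
survivor vs nonsurvivor). The package is aimed at bioinformaticians working
with whole-blood expression matrices (microarray-style log2 intensities)
who want a reproducible, scriptable version of this workflow, including a
synthetic-data generator so every stage can be exercised and validated
without any external download.

## The method

Given a genes × samples matrix `X` (log2 scale) with sample groups:

1. **Annotation.** Each immune gene is assigned one of 10 functional
   categories (adaptive immunity, innate immunity, NK cell activity,
   leukocyte migration, antigen presentation, complement-coagulation,
   platelet activity, cytokines-chemokines, signaling, hematopoiesis) by
   majority vote over its memberships in the 21 KEGG immune-system pathways
   plus optional GO/Reactome sets. Tie rules: a tie that mixes a broad
   category (cytokines-chemokines, signaling, hematopoiesis) with a
   specific one resolves to the specific one; any remaining tie is
   *undetermined* (U).
2. **Differential expression.** Per-gene Welch t-test (case vs control),
   Benjamini–Hochberg FDR, significance at q < 0.01.
3. **Gene-set enrichment.** A GAGE-style directional test: per case sample
   `j`, fold changes `f_ij = x_ij − mean(control_i)`; per pathway, a
   set-vs-complement t statistic per sample; one-sided p per direction;
   global p by Stouffer combination with a correlation correction
   (the per-sample scores share the control mean, giving equicorrelation
   ρ = 1/(n_ctrl+1)). Significance at global p < 0.05.
4. **Network construction.** Spearman correlations within one sample group;
   edge `(i, j)` iff ρ_ij ≥ 0.8 and p < 0.05 (two-sided t approximation,
   `t = ρ√((n−2)/(1−ρ²))`); isolated genes dropped.
5. **Topology.** Clustering coefficient `C_n = 2e_n/(k_n(k_n−1))`, density,
   heterogeneity (CV of degree), components, diameter, centralization,
   shortest-path count, characteristic path length, ⟨k⟩, N, degree
   assortativity μ and greedy-partition modularity Q — plus per-node degree,
   clustering, betweenness, closeness, stress, eccentricity and topological
   coefficient.
6. **Comparison.** Percent differences `(case − control)/control × 100` per
   parameter; detection of *prominent isolated clusters* (non-giant
   components dominated by one category, hypergeometric p < 0.05); and
   cross-dataset consensus tallies ("down-regulated in 5/6 datasets").

## Worked example

```python
from sepsisnet import (BlockSpec, SyntheticConfig, generate_dataset,
                       spearman_matrix, build_network,
                       compute_topology_report, detect_isolated_clusters)

categories = {i: ("adaptive immunity" if i < 12 else "innate immunity")
              for i in range(150)}
config = SyntheticConfig(
    n_genes=150, n_control=25, n_case=25,
    blocks=(BlockSpec(gene_indices=tuple(range(12)), rho_in=0.9,
                      active_group="case", category="adaptive immunity"),
            BlockSpec(gene_indices=tuple(range(12, 30)), rho_in=0.85,
                      active_group="both", category="innate immunity")),
    seed=3)
matrix, metadata, truth = generate_dataset(config)
annotation = {matrix.gene_ids[i]: c for i, c in categories.items()}

for group in ("control", "case"):
    net = build_network(spearman_matrix(matrix, group=group), annotation)
    print(group, net.number_of_nodes(), "nodes", net.number_of_edges(), "edges")
    for f in detect_isolated_clusters(net, annotation, min_size=5):
        print(f"  cluster: {f.size} genes, {f.dominant_category}, "
              f"p = {f.enrichment_p:.2e}, isolated = {f.is_isolated}")
```

prints

```
control 15 nodes 32 edges
case 30 nodes 211 edges
  cluster: 12 genes, adaptive immunity, p = 5.80e-18, isolated = True
```

The 12-gene adaptive-immunity block correlates only in the case group, so
the case network carries an extra dense, category-pure component — detached
from the giant component and flagged by the hypergeometric test — exactly
the "prominent and isolated cluster" pattern the comparison stage looks
for. Comparing the two topology reports with
`compare_reports(control_report, case_report)` then quantifies the change
in every parameter as a percent difference, e.g. a clustering-coefficient
pair (0.390, 0.337) gives −13.6% and a modularity pair (0.581, 0.694)
gives +19.4%.

The `examples/` directory contains one narrative script per capability
(simulation, annotation, DEG + enrichment, networks + topology, full
pipeline); each prints its results with a short interpretation. A thin CLI
mirrors the stages:

```bash
sepsisnet simulate --seed 7 --out sim/
sepsisnet deg --matrix sim/expression.tsv --metadata sim/metadata.tsv --out deg.tsv
sepsisnet run-all --seed 7 --out bundle/
```

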