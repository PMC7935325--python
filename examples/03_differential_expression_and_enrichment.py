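"""Per-gene differential expression and directional gene-set enrichment.

Simulates a dataset whose innate-immunity genes are shifted up in cases,
then runs the Welch t / BH-FDR gene test and the GAGE-style directional
pathway test (per-case-sample fold changes vs the control mean, set-vs-
complement t statistics, correlation-corrected Stouffer global p).
"""

from sepsisnet import SyntheticConfig, gage_enrichment, generate_dataset, welch_t
from sepsisnet.annotation import registry_from_annotation

n_genes = 400
categories = {i: ("innate immunity" if i < 40 else "signaling") for i in range(n_genes)}
config = SyntheticConfig(
    n_genes=n_genes,
    n_control=20,
    n_case=20,
    shift_genes=tuple((i, 1.0, 1) for i in range(40)),  # innate genes up in cases
    category_map=categories,
    seed=11,
)
matrix, _, truth = generate_dataset(config)
annotation = {matrix.gene_ids[i]: c for i, c in categories.items()}

deg = welch_t(matrix, fdr_threshold=0.01)
print(f"differentially expressed genes (q < 0.01): {int(deg.significant.sum())} "
      f"of {len(deg)} ({len(truth.de_genes)} planted)")

registry = registry_from_annotation(annotation)
enrichment = gage_enrichment(matrix, registry)
print("\npathway x direction results:")
print(
    enrichment[["pathway", "direction", "stat", "global_p", "significant"]]
    .to_string(index=False, float_format=lambda x: f"{x:.3g}")
)
# The planted innate-immunity set is flagged up-regulated with a tiny global
# p-value.  Note the test is relative (set vs complement): the untouched
# signaling genes are symmetrically flagged "down" because their fold changes
# sit below those of the shifted set — with only two pathways covering the
# panel, each is the other's background.  At the gene level, only a fraction
# of the 40 planted genes clear the stringent q < 0.01 cutoff at n = 20 per
# group; the set-level test aggregates the shared shift and is far more
# sensitive.
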