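"""Assign immune genes to functional categories by pathway majority vote.

Loads the shipped 21-pathway immune registry (reduced, representative gene
sets) and annotates every gene with one of 10 functional categories, or U
when the vote ties unresolvably.  Genes sitting in many pathways demonstrate
the tie rules: a tie between a specific category and one of the broad
{cytokines-chemokines, signaling, hematopoiesis} categories resolves to the
specific one.
"""

from sepsisnet import annotate_all, default_registry
from sepsisnet.annotation import category_frequency

registry = default_registry()
print(f"registry: {len(registry.pathways)} pathways, "
      f"{len(registry.gene_universe)} unique genes")

annotation = annotate_all(registry)
print("\ncategory frequencies:")
print(category_frequency(annotation).to_string())

for gene in ("LCK", "ITK", "SYK", "VAV1", "FGG"):
    pathways = [p.name for p in registry.pathways_of(gene)]
    print(f"\n{gene} -> {annotation[gene]}")
    print(f"  member of: {', '.join(pathways)}")
# LCK sits in three adaptive-leaning pathways and one NK pathway, so the
# majority vote lands on adaptive immunity; ITK's 1-1 tie between adaptive
# immunity and the broad cytokines-chemokines category resolves to adaptive.
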