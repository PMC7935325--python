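"""Immune pathway registry and gene-to-category annotation.

Each gene in the immune gene universe is assigned exactly one of ten
functional categories (or ``U`` for undetermined) by majority vote over its
pathway memberships across KEGG, GO and Reactome sets:

* the category with a strict majority of memberships wins;
* on a tie that mixes categories inside and outside the trio
  {cytokines-chemokines, signaling, hematopoiesis}, the trio categories are
  discarded and the vote re-evaluated — these three are broad "utility"
  annotations, so a more specific co-equal category takes precedence;
* any tie that survives (all-outside, all-inside, or multiple outsiders)
  yields ``U``.

All sources vote with equal weight; a gene appearing in three
adaptive-immunity pathways casts three adaptive votes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CATEGORIES: tuple[str, ...] = (
    "adaptive immunity",
    "antigen presentation",
    "cytokines-chemokines",
    "complement-coagulation",
    "hematopoiesis",
    "innate immunity",
    "leukocyte migration",
    "NK cell activity",
    "platelet activity",
    "signaling",
)

#: broad categories that lose mixed ties
TIE_EXCLUDED: frozenset[str] = frozenset(
    {"cytokines-chemokines", "signaling", "hematopoiesis"}
)

SOURCES = ("KEGG", "GO", "Reactome", "synthetic")

UNDETERMINED = "U"


@dataclass(frozen=True)
class Pathway:
    name: str
    source: str
    genes: frozenset[str]
    category: str


@dataclass
class PathwayRegistry:
    """Named immune gene sets, each mapped to one of the 10 categories."""

    pathways: dict[str, Pathway]

    def __post_init__(self) -> None:
        for p in self.pathways.values():
            if p.category not in CATEGORIES:
                raise ValueError(f"pathway {p.name!r} has unknown category {p.category!r}")
            if not p.genes:
                raise ValueError(f"pathway {p.name!r} has an empty gene set")
            if p.source not in SOURCES:
                raise ValueError(f"pathway {p.name!r} has unknown source {p.source!r}")

    @property
    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways.values():
            out |= p.genes
        return frozenset(out)

    @property
    def total_memberships(self) -> int:
        """Gene-pathway membership count (a gene in 3 pathways counts 3×)."""
        return sum(len(p.genes) for p in self.pathways.values())

    def from_source(self, source: str) -> dict[str, Pathway]:
        return {n: p for n, p in self.pathways.items() if p.source == source}

    def pathways_of(self, gene: str) -> list[Pathway]:
        return [p for p in self.pathways.values() if gene in p.genes]


def parse_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        sets[name] = frozenset(genes)
    return sets


def load_registry(
    gmt_paths: Iterable[str | Path], category_map_path: str | Path
) -> PathwayRegistry:
    """Load gene sets from GMT files and a category map TSV.

    The category map has columns ``pathway_name``, ``source``, ``category``
    and must cover every pathway found in the GMT files.
    """
    cmap = pd.read_csv(category_map_path, sep="\t", dtype=str)
    required = {"pathway_name", "source", "category"}
    if not required.issubset(cmap.columns):
        raise ValueError(f"category map must have columns {sorted(required)}")
    by_name = cmap.set_index("pathway_name")

    pathways: dict[str, Pathway] = {}
    for path in gmt_paths:
        for name, genes in parse_gmt(path).items():
            if name not in by_name.index:
                raise ValueError(f"pathway {name!r} missing from category map")
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            row = by_name.loc[name]
            pathways[name] = Pathway(
                name=name,
                source=str(row["source"]),
                genes=genes,
                category=str(row["category"]),
            )
    return PathwayRegistry(pathways=pathways)


def default_registry() -> PathwayRegistry:
    """The shipped registry: the 21 KEGG immune-system pathways mapped onto
    the 10 functional categories.

    Gene memberships are reduced, representative subsets (synthetic
    stand-ins for the full pathway lists) sufficient for testing the
    annotation, enrichment and network machinery; users analyzing real data
    should load complete GMT exports via :func:`load_registry`.
    """
    data = resources.files("sepsisnet") / "data"
    with resources.as_file(data / "kegg_immune_21_synthetic.gmt") as gmt, resources.as_file(
        data / "pathway_categories.tsv"
    ) as cmap:
        return load_registry([gmt], cmap)


def registry_from_annotation(annotation: Mapping[str, str]) -> PathwayRegistry:
    """One gene set per category from a gene → category mapping.

    Used for simulated data, where the generator's truth plays the role of
    the pathway database; ``U`` genes are left out.
    """
    by_cat: dict[str, set[str]] = {}
    for gene, cat in annotation.items():
        if cat == UNDETERMINED:
            continue
        by_cat.setdefault(cat, set()).add(gene)
    return PathwayRegistry(
        pathways={
            f"synthetic {cat}": Pathway(
                name=f"synthetic {cat}",
                source="synthetic",
                genes=frozenset(genes),
                category=cat,
            )
            for cat, genes in sorted(by_cat.items())
        }
    )


def assign_category(gene: str, registry: PathwayRegistry) -> str:
    """Majority-vote category for one gene; ``U`` on unresolved ties."""
    votes = Counter(p.category for p in registry.pathways_of(gene))
    if not votes:
        raise KeyError(f"gene {gene!r} absent from registry")
    top = max(votes.values())
    tied = sorted(c for c, v in votes.items() if v == top)
    if len(tied) == 1:
        return tied[0]
    outside = [c for c in tied if c not in TIE_EXCLUDED]
    inside = [c for c in tied if c in TIE_EXCLUDED]
    if outside and inside:
        # mixed tie: broad utility categories are removed, then re-evaluate
        if len(outside) == 1:
            return outside[0]
        return UNDETERMINED
    return UNDETERMINED


def annotate_all(registry: PathwayRegistry) -> dict[str, str]:
    """Label every gene in the registry's universe; total and deterministic."""
    return {g: assign_category(g, registry) for g in sorted(registry.gene_universe)}


def category_frequency(annotation: Mapping[str, str]) -> pd.Series:
    """Gene counts per assigned category (including U), sorted descending."""
    return pd.Series(Counter(annotation.values())).sort_values(ascending=False)


def write_annotation(annotation: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(annotation), "category": list(annotation.values())}
    ).sort_values("gene").to_csv(path, sep="\t", index=False)
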