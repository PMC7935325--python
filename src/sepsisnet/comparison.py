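"""Cross-condition network comparison.

Three kinds of summary:

* percent difference of topology parameters between a case-like and a
  control-like network, ``(case − control) / control × 100``;
* detection of *prominent isolated clusters* — connected components,
  separate from the giant component, dominated by one functional category
  beyond what a hypergeometric draw from the whole network would give;
* consensus across datasets: which genes recur in isolated clusters of a
  category, and how often a pathway is significant per direction
  (the "5/6 datasets" style tallies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .topology import REPORT_ROWS, TopologyReport


def percent_difference(case: float, control: float) -> float:
    """(case − control) / control × 100; control must be nonzero."""
    if control == 0:
        raise ZeroDivisionError("percent difference undefined for control = 0")
    return (case - control) / control * 100.0


def compare_reports(
    control: TopologyReport, case: TopologyReport
) -> pd.DataFrame:
    """Row-per-parameter comparison table with percent differences.

    Parameters undefined in either report (e.g. centralization on N < 3)
    yield a missing percent difference rather than an error, as does a zero
    control value.  ``direction`` is increased/decreased/unchanged.
    """
    rows = []
    c, s = control.to_dict(), case.to_dict()
    if set(c) != set(s):
        raise ValueError("mismatched parameter sets")
    for key, label in REPORT_ROWS.items():
        cv, sv = c[key], s[key]
        if cv is None or sv is None or cv == 0:
            pct = np.nan
        else:
            pct = percent_difference(float(sv), float(cv))
        if cv is None or sv is None:
            direction = "missing"
        elif sv > cv:
            direction = "increased"
        elif sv < cv:
            direction = "decreased"
        else:
            direction = "unchanged"
        rows.append(
            {
                "parameter": label,
                "control": cv,
                "case": sv,
                "percent_difference": pct,
                "percent_difference_display": round(pct, 1) if np.isfinite(pct) else None,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterFinding:
    nodes: frozenset[str]
    size: int
    dominant_category: str
    dominant_fraction: float
    enrichment_p: float
    is_isolated: bool


def detect_isolated_clusters(
    net: nx.Graph,
    annotation: Mapping[str, str],
    min_size: int = 5,
    alpha: float = 0.05,
    background: str = "annotation",
) -> list[ClusterFinding]:
    """Find category-dominated connected components.

    For every component of size >= ``min_size``, the dominant category's
    one-sided hypergeometric enrichment p is computed:
    p = P[X >= x], X ~ Hypergeom(N, K, n) with n the component size, x its
    dominant-category count, and (N, K) the gene total and category count of
    the chosen ``background`` — the full annotated gene panel by default
    (so a network reduced to a single pure-category component is still
    recognized as enriched), or the network's own nodes with
    ``background="network"``.  Components other than the largest are flagged
    isolated.  Findings with p < ``alpha`` are returned sorted by p (ties by
    first node ID).
    """
    if net.number_of_nodes() == 0:
        return []
    components = sorted(nx.connected_components(net), key=len, reverse=True)
    largest = components[0]
    cat_of = {v: annotation.get(v, net.nodes[v].get("category", "U")) for v in net.nodes}
    if background == "annotation":
        universe = dict(annotation)
        universe.update(cat_of)  # network nodes missing from the annotation
    elif background == "network":
        universe = cat_of
    else:
        raise ValueError(f"unknown background {background!r}")
    n_total = len(universe)
    background_counts = pd.Series(list(universe.values())).value_counts()

    findings = []
    for comp in components:
        if len(comp) < min_size:
            continue
        counts = pd.Series([cat_of[v] for v in comp]).value_counts()
        dominant = sorted(
            counts.index, key=lambda c: (-counts[c], c)
        )[0]
        x = int(counts[dominant])
        p = float(
            stats.hypergeom.sf(
                x - 1, n_total, int(background_counts[dominant]), len(comp)
            )
        )
        if p >= alpha:
            continue
        findings.append(
            ClusterFinding(
                nodes=frozenset(comp),
                size=len(comp),
                dominant_category=dominant,
                dominant_fraction=x / len(comp),
                enrichment_p=p,
                is_isolated=comp is not largest,
            )
        )
    findings.sort(key=lambda f: (f.enrichment_p, sorted(f.nodes)[0]))
    return findings


def cross_dataset_consensus(
    findings_per_dataset: Sequence[Sequence[ClusterFinding]],
    enrichment_per_dataset: Sequence[pd.DataFrame] | None = None,
    category: str | None = None,
) -> dict:
    """Consensus across >= 2 datasets.

    Returns a dict with:

    * ``gene_counts``: per gene, in how many datasets it appeared inside an
      isolated cluster (of ``category`` if given);
    * ``common_genes``: the genes present in all datasets' clusters;
    * ``pathway_tallies`` (when enrichment tables are given): per pathway ×
      direction, the number of datasets where it is significant.
    """
    n = len(findings_per_dataset)
    if n < 2:
        raise ValueError("consensus requires at least 2 datasets")
    per_dataset_genes: list[set[str]] = []
    for findings in findings_per_dataset:
        genes: set[str] = set()
        for f in findings:
            if not f.is_isolated:
                continue
            if category is not None and f.dominant_category != category:
                continue
            genes |= set(f.nodes)
        per_dataset_genes.append(genes)

    counts: dict[str, int] = {}
    for genes in per_dataset_genes:
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    common = sorted(g for g, k in counts.items() if k == n)

    out = {
        "n_datasets": n,
        "gene_counts": dict(sorted(counts.items())),
        "common_genes": common,
    }
    if enrichment_per_dataset is not None:
        tally: dict[tuple[str, str], int] = {}
        for table in enrichment_per_dataset:
            if table.empty:
                continue
            sig = table[table.significant]
            for _, row in sig.iterrows():
                key = (row.pathway, row.direction)
                tally[key] = tally.get(key, 0) + 1
        out["pathway_tallies"] = {
            f"{p} [{d}]": f"{k}/{n}" for (p, d), k in sorted(tally.items())
        }
    return out
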