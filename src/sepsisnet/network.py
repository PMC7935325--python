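"""Co-expression network construction.

Nodes are genes (tagged with their functional category); an undirected edge
joins two genes whose Spearman rank correlation within the selected sample
group passes ``rho >= rho_min`` (0.8 by default, signed — an ``absolute``
flag thresholds ``|rho|`` instead) with a two-sided p-value below ``alpha``
(0.05).  Degree-0 genes are dropped from the resulting graph, so reported
node counts refer to connected genes only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho and two-sided p-value matrices over genes."""

    gene_ids: list[str]
    rho: np.ndarray
    p: np.ndarray
    n_samples: int


def spearman_matrix(
    m: ExpressionMatrix,
    group: str | None = None,
    outcome: str | None = None,
) -> CorrelationMatrix:
    """All-pairs Spearman correlation within one sample group.

    ``group`` selects control/case samples; ``outcome`` selects
    survivor/nonsurvivor samples instead (exactly one may be given; neither
    means all samples).  Rho uses midranks for ties.  P-values come from the
    t approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` on n−2 degrees of
    freedom; |rho| = 1 is assigned p = 0.  Zero-variance genes get NaN
    rho/p against every partner and are excluded at network construction.
    """
    if group is not None and outcome is not None:
        raise ValueError("give group or outcome, not both")
    if group is not None:
        samples = m.samples_in_group(group)
    elif outcome is not None:
        samples = m.samples_with_outcome(outcome)
    else:
        samples = m.sample_ids
    n = len(samples)
    if n < 4:
        raise ValueError(f"need >=4 samples for correlation, got {n}")

    vals = m.values[samples].to_numpy()
    ranks = stats.rankdata(vals, axis=1)  # midranks
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d zero-variance gene(s); correlations undefined", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    # snap numerically-perfect monotone pairs to +/-1 so they get p = 0
    rho[np.abs(rho) > 1.0 - 1e-12] = np.sign(rho[np.abs(rho) > 1.0 - 1e-12])
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(gene_ids=m.gene_ids, rho=rho, p=p, n_samples=n)


def build_network(
    c: CorrelationMatrix,
    annotation: Mapping[str, str],
    rho_min: float = 0.8,
    alpha: float = 0.05,
    absolute: bool = False,
) -> nx.Graph:
    """Threshold a correlation matrix into a co-expression graph.

    Edge (i, j) exists iff ``rho_ij >= rho_min`` (or ``|rho_ij| >= rho_min``
    with ``absolute=True``) and ``p_ij < alpha``.  Nodes keep a ``category``
    attribute from ``annotation`` (``U`` if unannotated); genes left with no
    edge are not part of the graph.  An empty result is valid.
    """
    if not 0.0 < rho_min <= 1.0:
        raise ValueError("rho_min must be in (0, 1]")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    rho = np.abs(c.rho) if absolute else c.rho
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        keep = (rho >= rho_min) & (c.p < alpha)
    keep &= ~np.isnan(c.rho)
    iu = np.triu_indices(len(c.gene_ids), k=1)
    mask = keep[iu]

    g = nx.Graph()
    ids = c.gene_ids
    for i, j in zip(iu[0][mask], iu[1][mask]):
        g.add_edge(ids[i], ids[j], rho=float(c.rho[i, j]))
    nx.set_node_attributes(
        g, {node: annotation.get(node, "U") for node in g.nodes}, name="category"
    )
    if g.number_of_edges() == 0:
        logger.warning("no edges survive rho>=%s, p<%s", rho_min, alpha)
    return g


# ---------------------------------------------------------------------------
# Import/export
# ---------------------------------------------------------------------------

def export_network(net: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or an edge-table TSV.

    The TSV has columns gene_a, gene_b, rho plus a companion node table
    ``<path>.nodes.tsv`` (gene, category, degree); GraphML carries category
    as a node attribute and round-trips the graph exactly.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "tsv":
        edges = pd.DataFrame(
            [(a, b, d["rho"]) for a, b, d in net.edges(data=True)],
            columns=["gene_a", "gene_b", "rho"],
        )
        edges.to_csv(path, sep="\t", index=False)
        nodes = pd.DataFrame(
            [
                (node, net.nodes[node].get("category", "U"), net.degree[node])
                for node in sorted(net.nodes)
            ],
            columns=["gene", "category", "degree"],
        )
        nodes.to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'graphml' or 'tsv')")


def import_network(path: str | Path) -> nx.Graph:
    """Read back a GraphML network written by :func:`export_network`."""
    return nx.read_graphml(Path(path))
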