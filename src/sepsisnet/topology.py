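"""Global and per-node network topology metrics.

Implements the full parameter vector used to characterize immune
co-expression networks — clustering coefficient, density, heterogeneity,
connected components, diameter, centralization, shortest-path count,
characteristic path length, average degree, node count, degree correlation
and modularity — plus per-node centralities (degree, clustering,
betweenness, closeness, stress, eccentricity, topological coefficient).

Conventions follow the Cytoscape NetworkAnalyzer tool, the de-facto standard
for these reports:

* the network clustering coefficient averages over nodes of degree >= 2
  (nodes that cannot close a triangle are excluded by default);
* heterogeneity is the coefficient of variation of the degree distribution,
  sqrt(var(k))/mean(k) (a plain variance/mean variant is available);
* path metrics (diameter, characteristic path length, shortest-path count)
  are taken over *connected ordered* node pairs only, so multi-component
  graphs still yield finite values;
* betweenness is normalized by (N'−1)(N'−2)/2 within each component of size
  N'; stress counts geodesics over unordered endpoint pairs;
* centralization is the degree-based index (N/(N−2))·(k_max/(N−1) − density),
  1 for a star and 0 for any regular graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd

# Display row names for topology report tables
REPORT_ROWS = {
    "clustering_coefficient": "Clustering coefficient",
    "network_density": "Network density",
    "network_heterogeneity": "Network heterogeneity",
    "connected_components": "Connected components",
    "network_diameter": "Network diameter",
    "network_centralization": "Network centralization",
    "shortest_paths": "Shortest path",
    "characteristic_path_length": "Characteristic path length",
    "average_degree": "Average degree, <k>",
    "n_nodes": "Number of nodes, N",
    "degree_correlation": "Degree correlation, mu",
    "modularity": "Modularity, Mc",
}


@dataclass
class TopologyReport:
    clustering_coefficient: float
    network_density: float
    network_heterogeneity: float
    connected_components: int
    network_diameter: int
    network_centralization: float | None  # None when N < 3
    shortest_paths: int  # ordered connected pairs
    characteristic_path_length: float
    average_degree: float
    n_nodes: int
    degree_correlation: float | None  # None when degenerate (e.g. regular graph)
    modularity: float | None = None

    def to_dict(self) -> dict[str, float | int | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_table(self) -> pd.Series:
        d = self.to_dict()
        return pd.Series({REPORT_ROWS[k]: d[k] for k in REPORT_ROWS})


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def clustering(net: nx.Graph, include_low_degree: bool = False) -> tuple[dict, float]:
    """Per-node and network-average clustering coefficient.

    C_n = 2 e_n / (k_n (k_n − 1)) for k_n >= 2, else 0.  The network value
    averages nodes with k >= 2 unless ``include_low_degree`` is set, in
    which case degree-<2 nodes contribute 0.
    """
    per_node = nx.clustering(net)
    if include_low_degree:
        eligible = list(net.nodes)
    else:
        eligible = [v for v in net.nodes if net.degree[v] >= 2]
    avg = float(np.mean([per_node[v] for v in eligible])) if eligible else 0.0
    return per_node, avg


# ---------------------------------------------------------------------------
# Shortest-path machinery (shared by global metrics and centralities)
# ---------------------------------------------------------------------------

def _bfs_sigma(net: nx.Graph, source):
    """BFS distances and geodesic counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    order = [source]
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for w in net[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    nxt.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        order.extend(nxt)
        queue = nxt
    return dist, sigma, order


def _pairwise_distances(net: nx.Graph) -> dict:
    return {s: _bfs_sigma(net, s)[0] for s in net.nodes}


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------

def global_metrics(
    net: nx.Graph, heterogeneity_formula: str = "cv"
) -> TopologyReport:
    """The global topology parameter vector (modularity filled in separately).

    ``heterogeneity_formula`` is ``"cv"`` (sqrt(var(k))/mean(k), the
    NetworkAnalyzer convention) or ``"variance"`` (var(k)/mean(k)).
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("global metrics need at least 2 nodes")
    e = net.number_of_edges()
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    density = 2.0 * e / (n * (n - 1))
    mean_k = degrees.mean()
    var_k = degrees.var()  # population variance
    if mean_k == 0:
        heterogeneity = 0.0
    elif heterogeneity_formula == "cv":
        heterogeneity = float(np.sqrt(var_k) / mean_k)
    elif heterogeneity_formula == "variance":
        heterogeneity = float(var_k / mean_k)
    else:
        raise ValueError(f"unknown heterogeneity formula {heterogeneity_formula!r}")

    if n >= 3:
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
        centralization = float(centralization)
    else:
        centralization = None

    dists = _pairwise_distances(net)
    total = 0
    count = 0
    diameter = 0
    for s, dmap in dists.items():
        for t, d in dmap.items():
            if t == s:
                continue
            total += d
            count += 1
            if d > diameter:
                diameter = d

    try:
        with warnings.catch_warnings():
            # regular graphs have zero degree variance -> 0/0 inside networkx
            warnings.simplefilter("ignore", RuntimeWarning)
            assort = float(nx.degree_assortativity_coefficient(net))
        if not np.isfinite(assort):
            assort = None
    except (ValueError, ZeroDivisionError):
        assort = None

    _, avg_cc = clustering(net)
    return TopologyReport(
        clustering_coefficient=avg_cc,
        network_density=float(density),
        network_heterogeneity=heterogeneity,
        connected_components=nx.number_connected_components(net),
        network_diameter=diameter,
        network_centralization=centralization,
        shortest_paths=count,
        characteristic_path_length=(total / count) if count else 0.0,
        average_degree=float(mean_k),
        n_nodes=n,
        degree_correlation=assort,
    )


# ---------------------------------------------------------------------------
# Per-node centralities
# ---------------------------------------------------------------------------

def node_centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, clustering, betweenness, closeness, stress, eccentricity and
    topological coefficient for every node.

    Betweenness is Brandes-accumulated and normalized by (N'−1)(N'−2)/2
    within each connected component (0 for components smaller than 3);
    closeness is 1 / mean distance to reachable nodes; stress is the raw
    count of geodesics through the node over unordered endpoint pairs;
    eccentricity is the maximum distance within the node's component.
    """
    nodes = list(net.nodes)
    per_node_cc, _ = clustering(net)
    betweenness: dict = {}
    closeness: dict = {}
    eccentricity: dict = {}
    stress: dict = {v: 0.0 for v in nodes}

    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        nc = sub.number_of_nodes()
        bw = nx.betweenness_centrality(sub, normalized=nc >= 3)
        betweenness.update(bw)
        ecc = nx.eccentricity(sub)
        eccentricity.update(ecc)
        for v in comp:
            dmap = _bfs_sigma(sub, v)[0]
            sd = sum(dmap.values())
            closeness[v] = (nc - 1) / sd if sd > 0 else 0.0
        # stress: Brandes-style accumulation of raw geodesic counts.
        # After the sweep from source s, dstress(v) = sum over targets t
        # strictly beyond v of sigma_sv * sigma_vt, i.e. the number of s-t
        # geodesics with v interior; endpoints never contribute.
        for s in comp:
            dist, sigma, order = _bfs_sigma(sub, s)
            dstress = {v: 0.0 for v in order}
            for w in reversed(order):
                for u in sub[w]:
                    if dist[u] == dist[w] - 1:
                        dstress[u] += sigma[u] * (1.0 + dstress[w] / sigma[w])
            for v in order:
                if v != s:
                    stress[v] += dstress[v]
    # each unordered pair counted twice (once per endpoint as source)
    stress = {v: round(val / 2.0) for v, val in stress.items()}

    topo_coeff = topological_coefficient(net)
    return pd.DataFrame(
        {
            "degree": [net.degree[v] for v in nodes],
            "clustering": [per_node_cc[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "stress": [stress[v] for v in nodes],
            "eccentricity": [eccentricity[v] for v in nodes],
            "topological_coefficient": [topo_coeff[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def topological_coefficient(net: nx.Graph) -> dict:
    """T_n = mean over partners m (nodes sharing >= 1 neighbor with n) of
    (|N(n) ∩ N(m)| + [m adjacent to n]) / k_n; 0 when there are no partners
    or k_n = 0.
    """
    out = {}
    nbrs = {v: set(net[v]) for v in net.nodes}
    for v in net.nodes:
        k = len(nbrs[v])
        if k == 0:
            out[v] = 0.0
            continue
        scores = []
        for m in net.nodes:
            if m == v:
                continue
            shared = len(nbrs[v] & nbrs[m])
            if shared == 0:
                continue
            scores.append((shared + (1 if m in nbrs[v] else 0)) / k)
        out[v] = float(np.mean(scores)) if scores else 0.0
    return out


# ---------------------------------------------------------------------------
# Modularity and hubs
# ---------------------------------------------------------------------------

def modularity(net: nx.Graph, seed: int = 0) -> tuple[list[frozenset], float]:
    """Greedy (CNM) modularity-maximizing partition and its Newman–Girvan Q.

    The greedy agglomeration is deterministic; ``seed`` is accepted for API
    stability with randomized refinements.
    """
    if net.number_of_edges() == 0:
        raise ValueError("modularity requires at least one edge")
    communities = nx.community.greedy_modularity_communities(net)
    partition = sorted((frozenset(c) for c in communities), key=lambda c: sorted(c)[0])
    q = nx.community.modularity(net, partition)
    return partition, float(q)


def modularity_q(net: nx.Graph, partition) -> float:
    """Newman–Girvan Q of a given partition (exposed for worked examples)."""
    return float(nx.community.modularity(net, partition))


def find_hubs(net: nx.Graph, top_k: int = 1) -> list[tuple[str, int]]:
    """Top-``top_k`` nodes by degree (ties broken by node ID)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no hubs")
    ranked = sorted(net.degree(), key=lambda kv: (-kv[1], str(kv[0])))
    return [(str(v), int(d)) for v, d in ranked[:top_k]]


def compute_topology_report(net: nx.Graph, seed: int = 0, **kwargs) -> TopologyReport:
    """Global metrics plus modularity in one report."""
    report = global_metrics(net, **kwargs)
    if net.number_of_edges() > 0:
        _, q = modularity(net, seed=seed)
        report.modularity = q
    return report
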