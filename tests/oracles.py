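"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive: exhaustive triangle counting,
Floyd–Warshall distances, recursive enumeration of every geodesic, and a
by-hand Benjamini–Hochberg step-up.  These never share code with the
package's implementations.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


def oracle_clustering(net: nx.Graph) -> dict:
    """C_n by exhaustive enumeration of neighbor pairs."""
    out = {}
    for v in net.nodes:
        nbrs = list(net[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if net.has_edge(a, b))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def floyd_warshall(net: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in net.edges:
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return nodes, d


def all_geodesics(net: nx.Graph, d: np.ndarray, idx: dict, s, t) -> list[tuple]:
    """Every shortest s→t path, by recursive descent along the distance matrix."""
    if s == t:
        return [(s,)]
    paths = []
    for u in net[s]:
        if d[idx[u], idx[t]] == d[idx[s], idx[t]] - 1:
            paths.extend((s,) + p for p in all_geodesics(net, d, idx, u, t))
    return paths


def oracle_path_metrics(net: nx.Graph) -> dict:
    """Diameter, characteristic path length and ordered connected-pair count
    from the Floyd–Warshall matrix."""
    nodes, d = floyd_warshall(net)
    finite = np.isfinite(d) & ~np.eye(len(nodes), dtype=bool)
    dists = d[finite]
    return {
        "diameter": int(dists.max()) if dists.size else 0,
        "characteristic_path_length": float(dists.mean()) if dists.size else 0.0,
        "shortest_paths": int(finite.sum()),
    }


def oracle_centralities(net: nx.Graph) -> dict:
    """Betweenness (normalized within components), stress, closeness and
    eccentricity from full geodesic enumeration."""
    nodes, d = floyd_warshall(net)
    idx = {v: i for i, v in enumerate(nodes)}
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not np.isfinite(d[idx[s], idx[t]]):
            continue
        paths = all_geodesics(net, d, idx, s, t)
        for v in nodes:
            if v == s or v == t:
                continue
            through = sum(1 for p in paths if v in p)
            stress[v] += through
            bet[v] += through / len(paths)
    comp_of = {}
    for comp in nx.connected_components(net):
        for v in comp:
            comp_of[v] = comp
    betweenness = {}
    for v in nodes:
        nc = len(comp_of[v])
        scale = (nc - 1) * (nc - 2) / 2.0
        betweenness[v] = bet[v] / scale if scale > 0 else 0.0

    closeness = {}
    eccentricity = {}
    for v in nodes:
        dv = d[idx[v]]
        reach = [dv[idx[u]] for u in comp_of[v] if u != v]
        closeness[v] = 1.0 / float(np.mean(reach)) if reach else 0.0
        eccentricity[v] = int(max(reach)) if reach else 0
    return {
        "betweenness": betweenness,
        "stress": stress,
        "closeness": closeness,
        "eccentricity": eccentricity,
    }


def oracle_topological_coefficient(net: nx.Graph) -> dict:
    out = {}
    for v in net.nodes:
        k = net.degree[v]
        if k == 0:
            out[v] = 0.0
            continue
        vals = []
        for m in net.nodes:
            if m == v:
                continue
            shared = len(set(net[v]) & set(net[m]))
            if shared:
                vals.append((shared + (1 if net.has_edge(v, m) else 0)) / k)
        out[v] = sum(vals) / len(vals) if vals else 0.0
    return out


def oracle_bh(pvalues) -> np.ndarray:
    """Step-up BH by the textbook definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def oracle_hypergeom_tail(x: int, n_total: int, k_cat: int, n_draw: int) -> float:
    """P[X >= x] by explicit combinatorial summation."""
    denom = comb(n_total, n_draw)
    return sum(
        comb(k_cat, j) * comb(n_total - k_cat, n_draw - j)
        for j in range(x, min(k_cat, n_draw) + 1)
    ) / denom


def oracle_degree_assortativity(net: nx.Graph):
    """Pearson correlation of endpoint degrees over the edge list, both
    orientations; None when a degenerate (zero-variance) degree sequence
    makes it undefined."""
    xs, ys = [], []
    for a, b in net.edges:
        xs += [net.degree[a], net.degree[b]]
        ys += [net.degree[b], net.degree[a]]
    if not xs:
        return None
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def oracle_newman_q(net: nx.Graph, partition) -> float:
    """Q = sum_c (e_c/m - (d_c/2m)^2) computed directly from definitions."""
    m = net.number_of_edges()
    q = 0.0
    for community in partition:
        community = set(community)
        within = sum(1 for a, b in net.edges if a in community and b in community)
        degree_sum = sum(net.degree[v] for v in community)
        q += within / m - (degree_sum / (2.0 * m)) ** 2
    return q


def random_test_graph(rng: np.random.Generator, n_max: int = 40) -> nx.Graph:
    """A random graph of mixed density, possibly disconnected."""
    n = int(rng.integers(5, n_max + 1))
    p = float(rng.uniform(0.05, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return g
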