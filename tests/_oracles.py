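"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own shortest-path and pair-counting
code paths: distances come from a rebuilt networkx graph with the query
points inserted as explicit nodes, and every statistic is recomputed with
plain double loops.
"""

import itertools

import networkx as nx
import numpy as np


def _augmented_graph(net, locations):
    """networkx Graph over net's nodes plus one explicit node per location,
    each edge split at the locations it carries."""
    g = nx.MultiGraph()
    g.add_nodes_from(range(net.n_nodes))
    by_edge = {}
    for label, (eid, off) in locations.items():
        by_edge.setdefault(eid, []).append((float(off), label))
    for e in net.edges:
        pts = sorted(by_edge.get(e.edge_id, []))
        chain = [(0.0, e.node_a)] + pts + [(e.length, e.node_b)]
        for (o1, u), (o2, v) in zip(chain, chain[1:]):
            g.add_edge(u, v, weight=max(o2 - o1, 0.0))
    return g


def brute_distance(net, a, b):
    """Shortest-path distance between two (edge, offset) locations via an
    explicitly rebuilt graph."""
    g = _augmented_graph(net, {"A": a, "B": b})
    try:
        return nx.shortest_path_length(g, "A", "B", weight="weight")
    except nx.NetworkXNoPath:
        return float("inf")


def brute_equal_split(net, q, i, kernel):
    """Per-pair equal-split kernel: enumerate all shortest paths from the
    event i to the evaluation point q, pick the lexicographically smallest
    sequence of original node ids, and divide the base kernel by the
    product of (degree - 1) over those intermediate nodes."""
    g = _augmented_graph(net, {"Q": q, "I": i})
    try:
        d = nx.shortest_path_length(g, "I", "Q", weight="weight")
    except nx.NetworkXNoPath:
        return 0.0
    if d > kernel.bandwidth_m:
        return 0.0
    best = min(tuple(n for n in path if isinstance(n, (int, np.integer)))
               for path in nx.all_shortest_paths(g, "I", "Q", weight="weight"))
    prod = 1.0
    for v in best:
        prod *= net.degree(int(v)) - 1
    if prod <= 0:
        return 0.0
    return float(kernel.evaluate(d)) / prod


def brute_cross_k(net, events_b, points_a, d_grid):
    """Cross K by exhaustive pair enumeration with oracle distances."""
    locs_a = points_a.locations()
    locs_b = events_b.locations()
    dists = [brute_distance(net, a, b)
             for a, b in itertools.product(locs_a, locs_b)]
    L = net.total_length
    n_a, n_b = len(locs_a), len(locs_b)
    rho = n_b / L
    return np.array([sum(dd < d for dd in dists if np.isfinite(dd))
                     / (rho * n_a) for d in d_grid])


def brute_local_moran(z, w):
    n = len(z)
    return np.array([z[i] * sum(w[i][j] * z[j] for j in range(n))
                     for i in range(n)])


# -- concordance statistics, all by explicit double loops -------------------

def _sgn(x):
    return int(x > 0) - int(x < 0)


def brute_concordance(v1, v2, i, j):
    return _sgn(v1[i] - v1[j]) * _sgn(v2[i] - v2[j])


def brute_tau(v1, v2):
    n = len(v1)
    c = d = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            s = brute_concordance(v1, v2, i, j)
            c += s == 1
            d += s == -1
    return (c - d) / (n * (n - 1) / 2), c, d


def brute_tau_prime(v1, v2):
    n = len(v1)
    c = d = e1 = e2 = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            s1 = _sgn(v1[i] - v1[j])
            s2 = _sgn(v2[i] - v2[j])
            c += s1 * s2 == 1
            d += s1 * s2 == -1
            e1 += s1 != 0 and s2 == 0
            e2 += s1 == 0 and s2 != 0
    denom = (c + d + e1) * (c + d + e2)
    return (c - d) / np.sqrt(denom) if denom else None


def brute_tau_w(v1, v2, w):
    n = len(v1)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i][j] * brute_concordance(v1, v2, i, j)
            den += w[i][j]
    return num / den


def brute_lima_local(v1, v2):
    n = len(v1)
    return np.array([sum(brute_concordance(v1, v2, i, j)
                         for j in range(n) if j != i) / (n - 1)
                     for i in range(n)])


def brute_lima_neighbor(v1, v2, w):
    n = len(v1)
    out = np.full(n, np.nan)
    for i in range(n):
        den = sum(w[i])
        if den:
            out[i] = sum(w[i][j] * brute_concordance(v1, v2, i, j)
                         for j in range(n)) / den
    return out


def brute_lima_neighborhood(v1, v2, w):
    n = len(v1)
    out = np.full(n, np.nan)
    for i in range(n):
        ns = [j for j in range(n) if w[i][j]] + [i]
        m = len(ns)
        if m < 2:
            continue
        tot = sum(brute_concordance(v1, v2, a, b)
                  for a in ns for b in ns if a != b)
        out[i] = tot / (m * (m - 1))
    return out
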