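"""Independent brute-force oracles for small graphs and small universes.

Everything here is deliberately naive — exhaustive path enumeration,
subset enumeration, combinatorial draws — so it shares no code path with
the implementations it checks. Only usable on tiny inputs.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

TOL = 1e-9


def _edge_length(g: nx.Graph, u, v) -> float:
    d = g[u][v]
    rho = d.get("rho", 1.0)
    return 1.0 / abs(rho)


def all_min_weight_paths(g: nx.Graph, s, t) -> tuple[float, list[list]]:
    """All minimal-total-length simple paths s→t by full enumeration."""
    best, paths = float("inf"), []
    for path in nx.all_simple_paths(g, s, t):
        w = sum(_edge_length(g, a, b) for a, b in zip(path, path[1:]))
        if w < best - TOL:
            best, paths = w, [path]
        elif abs(w - best) <= TOL:
            paths.append(path)
    return best, paths


def brute_betweenness(g: nx.Graph) -> dict:
    """Normalised weighted betweenness via exhaustive path enumeration."""
    n = g.number_of_nodes()
    bc = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes(), 2):
        if not nx.has_path(g, s, t):
            continue
        _, paths = all_min_weight_paths(g, s, t)
        sigma = len(paths)
        for v in g:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / sigma
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        bc = {v: x / norm for v, x in bc.items()}
    return bc


def brute_closeness(g: nx.Graph) -> dict:
    """Wasserman–Faust closeness from enumerated shortest distances."""
    n = g.number_of_nodes()
    out = {}
    for v in g:
        dists = []
        for u in g:
            if u == v or not nx.has_path(g, v, u):
                continue
            d, _ = all_min_weight_paths(g, v, u)
            dists.append(d)
        r = len(dists)
        out[v] = (r / sum(dists)) * (r / (n - 1)) if r else 0.0
    return out


def brute_avg_shortest_path(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        dists = [all_min_weight_paths(g, v, u)[0]
                 for u in g if u != v and nx.has_path(g, v, u)]
        out[v] = sum(dists) / len(dists) if dists else 0.0
    return out


def brute_clustering(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        nbrs = list(g[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def brute_topological_coefficient(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        nv = set(g[v])
        if not nv:
            out[v] = 0.0
            continue
        vals = []
        for u in g:
            if u == v:
                continue
            shared = nv & set(g[u])
            if not shared:
                continue
            vals.append((len(shared) + (1 if g.has_edge(u, v) else 0))
                        / len(nv))
        out[v] = sum(vals) / len(vals) if vals else 0.0
    return out


def brute_triangle_list(g: nx.Graph) -> list[tuple]:
    return [tuple(sorted(t)) for t in combinations(sorted(g.nodes()), 3)
            if g.has_edge(t[0], t[1]) and g.has_edge(t[0], t[2])
            and g.has_edge(t[1], t[2])]


def brute_mcode_weight(g: nx.Graph, v, degree_cutoff: int = 2) -> float:
    """MCODE vertex weight by exhaustive subset search for the k-core.

    The k-core of a graph is the union of all vertex subsets whose
    induced subgraph has minimum degree ≥ k; enumerate subsets to find
    the largest k with a non-empty core and that core's density.
    """
    if g.degree(v) < degree_cutoff:
        return 0.0
    closed = g.subgraph(set(g[v]) | {v})
    nodes = list(closed.nodes())
    best_k = 0
    for k in range(1, len(nodes)):
        members: set = set()
        for r in range(k + 1, len(nodes) + 1):
            for sub in combinations(nodes, r):
                h = closed.subgraph(sub)
                if min(dict(h.degree()).values()) >= k:
                    members |= set(sub)
        if members:
            best_k = k
            core = closed.subgraph(members)
        else:
            break
    if best_k == 0:
        return 0.0
    n, e = core.number_of_nodes(), core.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    return best_k * density


def brute_hypergeom_upper(universe_size: int, set_size: int,
                          query_size: int, overlap: int) -> float:
    """P(overlap ≥ k) by enumerating all possible query draws."""
    from math import comb

    total = comb(universe_size, query_size)
    hits = 0
    for x in range(overlap, min(set_size, query_size) + 1):
        hits += comb(set_size, x) * comb(universe_size - set_size,
                                         query_size - x)
    return hits / total
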