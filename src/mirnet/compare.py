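"""Cross-condition network comparison, motif census and neighbourhoods.

Edge identity across networks is the unordered miRNA-id pair; weights may
differ. "Preservation" against a reference dataset recomputes significance
in the reference correlation table at the same alpha rather than
intersecting fixed edge lists, and "concordance" additionally requires the
correlation sign to match.

The motif census classifies connected components into the small shapes
used to describe sparse networks: isolated node, pair (a single edge),
triangle (K3), chain (induced path of ≥ 3 nodes) and other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from mirnet.network import CoexpressionNetwork, CorrelationTable


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoexpressionNetwork) else net


def _edge_pairs(g: nx.Graph) -> set[tuple[str, str]]:
    return {tuple(sorted((a, b))) for a, b in g.edges()}


@dataclass
class ComparisonReport:
    shared_nodes: set[str]
    nodes_only_a: set[str]
    nodes_only_b: set[str]
    shared_edges: set[tuple[str, str]]
    edges_only_a: set[tuple[str, str]]
    edges_only_b: set[tuple[str, str]]
    nodes_with_no_shared_links: set[str]
    nodes_with_all_links_shared: set[str]


def compare_networks(net_a, net_b) -> ComparisonReport:
    """Set algebra between two networks on node ids and unordered edges.

    A shared node has "no shared links" when its incident edge sets in the
    two networks are disjoint, and "all links shared" when they coincide
    exactly (both non-empty).
    """
    ga, gb = _as_graph(net_a), _as_graph(net_b)
    na, nb = set(ga.nodes()), set(gb.nodes())
    ea, eb = _edge_pairs(ga), _edge_pairs(gb)
    shared_nodes = na & nb
    no_shared, all_shared = set(), set()
    for v in shared_nodes:
        inc_a = {tuple(sorted((v, w))) for w in ga[v]}
        inc_b = {tuple(sorted((v, w))) for w in gb[v]}
        if not (inc_a or inc_b):
            continue  # isolated in both: neither category
        if not inc_a & inc_b:
            no_shared.add(v)
        elif inc_a == inc_b:
            all_shared.add(v)
    return ComparisonReport(
        shared_nodes=shared_nodes,
        nodes_only_a=na - nb,
        nodes_only_b=nb - na,
        shared_edges=ea & eb,
        edges_only_a=ea - eb,
        edges_only_b=eb - ea,
        nodes_with_no_shared_links=no_shared,
        nodes_with_all_links_shared=all_shared)


@dataclass
class PreservationResult:
    preserved: int
    concordant: int
    absent_from_reference: int
    n_query_edges: int


def preservation_vs_reference(query, ref_corr: CorrelationTable,
                              alpha: float = 0.05) -> PreservationResult:
    """Count query edges replicated in an independent correlation table.

    An edge is *preserved* when the same miRNA pair is significant
    (p < alpha) in the reference table, and *concordant* when its
    correlation sign also matches. Pairs with an endpoint missing from
    the reference feature space count as unpreserved and are tallied
    separately.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    g = _as_graph(query)
    ref_feats = set(ref_corr.rho.index)
    preserved = concordant = absent = 0
    for a, b, d in g.edges(data=True):
        if a not in ref_feats or b not in ref_feats:
            absent += 1
            continue
        if ref_corr.p.loc[a, b] < alpha:
            preserved += 1
            rho_q = d.get("rho", 1.0)
            if rho_q * ref_corr.rho.loc[a, b] > 0:
                concordant += 1
    return PreservationResult(preserved=preserved, concordant=concordant,
                              absent_from_reference=absent,
                              n_query_edges=g.number_of_edges())


MOTIF_CLASSES = ("isolated", "pair", "triangle", "chain", "other")


@dataclass
class MotifCensus:
    counts: dict[str, int]
    components: list[tuple[str, frozenset[str]]]
    triangles: list[tuple[str, str, str]]
    longest_chain: list[str] = field(default_factory=list)
    longest_chain_signs: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return sum(self.counts.values())


def _classify_component(sub: nx.Graph) -> str:
    n, e = sub.number_of_nodes(), sub.number_of_edges()
    if n == 1:
        return "isolated"
    if n == 2:
        return "pair"
    if n == 3 and e == 3:
        return "triangle"
    degrees = sorted(d for _, d in sub.degree())
    if e == n - 1 and degrees[:2] == [1, 1] and all(
            d == 2 for d in degrees[2:]):
        return "chain"
    return "other"


def _chain_order(sub: nx.Graph) -> list[str]:
    ends = sorted(v for v, d in sub.degree() if d == 1)
    start = ends[0]
    order, prev, cur = [start], None, start
    while True:
        nxts = [w for w in sub[cur] if w != prev]
        if not nxts:
            break
        prev, cur = cur, nxts[0]
        order.append(cur)
    return order


def motif_census(net) -> MotifCensus:
    """Classify components and enumerate triangles anywhere in the graph.

    Triangles are found by ordered adjacency intersection (each triple
    reported once, sorted). The longest chain-classified component is
    returned as an ordered node list from its lexicographically smaller
    end, together with the direct/inverse sign sequence along its edges.
    """
    g = _as_graph(net)
    counts = {c: 0 for c in MOTIF_CLASSES}
    components: list[tuple[str, frozenset[str]]] = []
    best_chain: list[str] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        cls = _classify_component(sub)
        counts[cls] += 1
        components.append((cls, frozenset(comp)))
        if cls == "chain":
            order = _chain_order(sub)
            if len(order) > len(best_chain):
                best_chain = order

    triangles = []
    adj = {v: {w for w in g[v] if w > v} for v in g}
    for a in sorted(g.nodes()):
        for b in sorted(adj[a]):
            for c in sorted(adj[a] & adj[b]):
                triangles.append((a, b, c))

    signs = []
    for u, v in zip(best_chain, best_chain[1:]):
        d = g.get_edge_data(u, v, default={})
        signs.append(d.get("sign",
                           "direct" if d.get("rho", 1.0) > 0 else "inverse"))
    components.sort(key=lambda t: sorted(t[1])[0])
    return MotifCensus(counts=counts, components=components,
                       triangles=triangles, longest_chain=best_chain,
                       longest_chain_signs=signs)


@dataclass
class Neighbourhood:
    centre: str
    radius: int
    graph: nx.Graph
    neighbours: dict[str, tuple[float, str]]  # direct neighbours: rho, sign


def neighbourhood(net, centre: str, radius: int = 1) -> Neighbourhood:
    """Breadth-limited subgraph around ``centre`` with edge annotations."""
    g = _as_graph(net)
    if centre not in g:
        raise KeyError(f"unknown centre node {centre!r}")
    if radius < 1:
        raise ValueError(f"radius must be ≥ 1, got {radius}")
    ego = nx.ego_graph(g, centre, radius=radius)
    direct = {}
    for w in g[centre]:
        d = g[centre][w]
        rho = float(d.get("rho", 1.0))
        direct[w] = (rho, d.get("sign",
                                "direct" if rho > 0 else "inverse"))
    return Neighbourhood(centre=centre, radius=radius, graph=ego,
                         neighbours=direct)


def comparison_to_frame(report: ComparisonReport):
    import pandas as pd

    rows = [
        ("shared_nodes", len(report.shared_nodes)),
        ("nodes_only_a", len(report.nodes_only_a)),
        ("nodes_only_b", len(report.nodes_only_b)),
        ("shared_edges", len(report.shared_edges)),
        ("edges_only_a", len(report.edges_only_a)),
        ("edges_only_b", len(report.edges_only_b)),
        ("nodes_with_no_shared_links",
         len(report.nodes_with_no_shared_links)),
        ("nodes_with_all_links_shared",
         len(report.nodes_with_all_links_shared)),
    ]
    return pd.DataFrame(rows, columns=["quantity", "count"])
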