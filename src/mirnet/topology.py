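"""Global geometric attributes and local node centralities.

Two distance conventions coexist, mirroring the attribute panels of common
network viewers on one hand and correlation-weighted centralities on the
other:

* global attributes (diameter, characteristic path length, shortest-path
  counts) are computed on the *unweighted* graph;
* local centralities (betweenness, closeness, per-node average shortest
  path) measure path length as the sum of inverse edge weights ``1/|rho|``,
  so strongly correlated miRNAs are close regardless of correlation sign.

Centralization is Freeman degree centralization; heterogeneity is the
coefficient of variation of the degree distribution.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from mirnet.network import CoexpressionNetwork


@dataclass(frozen=True)
class GlobalTopology:
    n_nodes: int
    n_edges: int
    connected_components: int
    diameter: int
    n_shortest_paths: int          # ordered reachable pairs
    shortest_paths_fraction: float  # of N(N−1)
    characteristic_path_length: float
    network_centralization: float
    avg_neighbours: float
    density: float
    heterogeneity: float


@dataclass(frozen=True)
class NodeTopology:
    mirna: str
    degree: int
    betweenness: float
    closeness: float
    clustering_coefficient: float
    topological_coefficient: float
    avg_shortest_path: float
    asp_defined: bool  # False for nodes with no reachable partner


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, CoexpressionNetwork) else net


def _edge_lengths(g: nx.Graph) -> nx.Graph:
    """Copy with a ``length`` attribute = 1/|rho| (1 if no rho given)."""
    h = g.copy()
    for a, b, d in h.edges(data=True):
        rho = d.get("rho", 1.0)
        if rho == 0:
            raise ValueError(f"edge ({a},{b}) has zero weight")
        d["length"] = 1.0 / abs(rho)
    return h


def global_topology(net) -> GlobalTopology:
    """Global geometric attributes of a network (unweighted paths)."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError(f"global topology needs ≥ 2 nodes, got {n}")
    e = g.number_of_edges()
    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    diameter = (nx.diameter(g.subgraph(largest)) if len(largest) > 1 else 0)

    total_dist = 0
    n_pairs = 0
    for comp in components:
        if len(comp) < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(g.subgraph(comp)):
            total_dist += sum(dists.values())
            n_pairs += len(dists) - 1  # exclude self
    cpl = total_dist / n_pairs if n_pairs else 0.0

    density = 2.0 * e / (n * (n - 1))
    degrees = [d for _, d in g.degree()]
    max_deg = max(degrees)
    centralization = (0.0 if n == 2
                      else (n / (n - 2)) * (max_deg / (n - 1) - density))
    mean_deg = 2.0 * e / n
    heterogeneity = (float(np.std(degrees) / mean_deg) if mean_deg > 0
                     else 0.0)
    return GlobalTopology(
        n_nodes=n, n_edges=e,
        connected_components=len(components),
        diameter=diameter,
        n_shortest_paths=n_pairs,
        shortest_paths_fraction=n_pairs / (n * (n - 1)),
        characteristic_path_length=cpl,
        network_centralization=centralization,
        avg_neighbours=mean_deg,
        density=density,
        heterogeneity=heterogeneity)


def topological_coefficient(g: nx.Graph, v) -> float:
    """Average shared-neighbour ratio of ``v``.

    Over every other node ``u`` sharing at least one neighbour with ``v``,
    averages ``J(v,u)/k(v)`` where ``J(v,u)`` counts shared neighbours,
    plus one when ``u`` and ``v`` are adjacent. Zero when nothing is
    shared.
    """
    nv = set(g[v])
    k = len(nv)
    if k == 0:
        return 0.0
    ratios = []
    for u in g:
        if u == v:
            continue
        shared = len(nv & set(g[u]))
        if shared == 0:
            continue
        j = shared + (1 if g.has_edge(u, v) else 0)
        ratios.append(j / k)
    return statistics.fmean(ratios) if ratios else 0.0


def node_topology(net) -> list[NodeTopology]:
    """Per-node centralities with inverse-|rho| path lengths.

    Betweenness is normalised by the ordered non-involved pair count;
    closeness uses the Wasserman–Faust form, which stays in [0,1] on
    disconnected graphs; the clustering coefficient ignores weights.
    Isolated nodes receive zeros with ``asp_defined=False``.
    """
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("node topology needs ≥ 2 nodes")
    h = _edge_lengths(g)
    betweenness = nx.betweenness_centrality(h, weight="length",
                                            normalized=True)
    closeness = nx.closeness_centrality(h, distance="length",
                                        wf_improved=True)
    clustering = nx.clustering(g)
    reports = []
    for v in g.nodes():
        dists = nx.single_source_dijkstra_path_length(h, v, weight="length")
        dists.pop(v, None)
        defined = len(dists) > 0
        asp = float(np.mean(list(dists.values()))) if defined else 0.0
        reports.append(NodeTopology(
            mirna=v,
            degree=g.degree(v),
            betweenness=float(betweenness[v]),
            closeness=float(closeness[v]),
            clustering_coefficient=float(clustering[v]),
            topological_coefficient=topological_coefficient(g, v),
            avg_shortest_path=asp,
            asp_defined=defined))
    return reports


RANKED_INDICES = ("degree", "betweenness", "closeness",
                  "clustering_coefficient", "topological_coefficient",
                  "avg_shortest_path")


@dataclass
class RankResult:
    """Top-k nodes per topological index.

    ``per_index`` holds, for each index, the k best nodes (descending
    value, ties broken by id) plus any node tied with the k-th value;
    nodes beyond rank k included through such a tie are listed in
    ``boundary_ties``. ``in_any`` / ``in_multiple`` collect nodes top-k in
    at least one / more than one index.
    """

    k: int
    per_index: dict[str, list[str]]
    boundary_ties: dict[str, set[str]]
    in_any: set[str]
    in_multiple: set[str]


def rank_nodes(reports: list[NodeTopology], k: int,
               indices: tuple[str, ...] = RANKED_INDICES) -> RankResult:
    if k < 1:
        raise ValueError(f"k must be ≥ 1, got {k}")
    per_index: dict[str, list[str]] = {}
    ties: dict[str, set[str]] = {}
    membership: dict[str, int] = {}
    for idx in indices:
        ordered = sorted(reports, key=lambda r: (-getattr(r, idx), r.mirna))
        cut = min(k, len(ordered))
        boundary = getattr(ordered[cut - 1], idx)
        chosen = [r.mirna for r in ordered[:cut]]
        tied = {r.mirna for r in ordered[cut:]
                if getattr(r, idx) == boundary}
        per_index[idx] = chosen + sorted(tied)
        ties[idx] = tied | ({r.mirna for r in ordered[:cut]
                             if getattr(r, idx) == boundary}
                            if tied else set())
        for m in per_index[idx]:
            membership[m] = membership.get(m, 0) + 1
    return RankResult(
        k=k, per_index=per_index, boundary_ties=ties,
        in_any={m for m, c in membership.items() if c >= 1},
        in_multiple={m for m, c in membership.items() if c > 1})


def node_report_frame(reports: list[NodeTopology]) -> pd.DataFrame:
    return (pd.DataFrame([r.__dict__ for r in reports])
            .sort_values("mirna").reset_index(drop=True))


def global_report_frame(g: GlobalTopology) -> pd.DataFrame:
    return pd.DataFrame([g.__dict__])
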