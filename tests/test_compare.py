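"""Network comparison, motif census and neighbourhood extraction."""

import networkx as nx
import pytest

from mirnet.compare import (compare_networks, preservation_vs_reference,
                            motif_census, neighbourhood)
from mirnet.network import spearman_matrix, build_network, CorrelationTable
from mirnet.simulate import SimulationConfig, ModuleSpec, simulate_study
from conftest import net_from_edges, random_weighted_graph
import oracles


def test_identical_networks_share_everything():
    net = net_from_edges([("a", "b"), ("b", "c")], nodes=["a", "b", "c", "d"])
    rep = compare_networks(net, net)
    assert rep.shared_nodes == {"a", "b", "c", "d"}
    assert not rep.nodes_only_a and not rep.nodes_only_b
    assert rep.shared_edges == {("a", "b"), ("b", "c")}
    assert not rep.edges_only_a
    assert rep.nodes_with_all_links_shared == {"a", "b", "c"}
    assert rep.nodes_with_no_shared_links == set()


def test_edge_disjoint_networks():
    a = net_from_edges([("x", "y")], nodes=["x", "y", "z"])
    b = net_from_edges([("y", "z")], nodes=["x", "y", "z"])
    rep = compare_networks(a, b)
    assert rep.shared_edges == set()
    assert rep.nodes_with_no_shared_links == {"x", "y", "z"}


def test_comparison_symmetric_under_swap():
    a = net_from_edges([("a", "b"), ("b", "c")], nodes=list("abcx"))
    b = net_from_edges([("b", "c"), ("c", "d")], nodes=list("bcdy"))
    fwd, rev = compare_networks(a, b), compare_networks(b, a)
    assert fwd.shared_nodes == rev.shared_nodes
    assert fwd.shared_edges == rev.shared_edges
    assert fwd.nodes_only_a == rev.nodes_only_b
    assert fwd.edges_only_a == rev.edges_only_b


def test_hand_enumerated_counts():
    a = net_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
    b = net_from_edges([("a", "b"), ("c", "d"), ("e", "f")])
    rep = compare_networks(a, b)
    assert rep.shared_nodes == {"a", "b", "c", "d", "e"}
    assert rep.nodes_only_b == {"f"}
    assert rep.shared_edges == {("a", "b"), ("c", "d")}
    # "e" is linked in both networks (d–e vs e–f) with nothing in common
    assert rep.nodes_with_no_shared_links == {"e"}
    assert rep.nodes_with_all_links_shared == {"a"}


def test_self_preservation_and_sign_flip(rng):
    import numpy as np
    from conftest import make_study
    vals = rng.normal(size=(8, 30))
    study = make_study(vals, n_pairs=15)
    corr = spearman_matrix(study, tissue="tumour")
    net = build_network(corr, alpha=0.05)
    res = preservation_vs_reference(net, corr, alpha=0.05)
    assert res.preserved == net.n_edges
    assert res.concordant == net.n_edges
    flipped = CorrelationTable(-corr.rho, corr.p, corr.n_samples)
    res2 = preservation_vs_reference(net, flipped, alpha=0.05)
    assert res2.preserved == net.n_edges
    assert res2.concordant == 0


def test_preservation_counts_missing_features(rng):
    from conftest import make_study
    vals = rng.normal(size=(6, 20))
    study = make_study(vals, n_pairs=10)
    corr = spearman_matrix(study, tissue="tumour")
    net = build_network(corr, alpha=0.2)
    reduced = CorrelationTable(corr.rho.iloc[:3, :3], corr.p.iloc[:3, :3],
                               corr.n_samples)
    res = preservation_vs_reference(net, reduced, alpha=0.2)
    assert res.preserved + res.absent_from_reference <= res.n_query_edges
    assert res.concordant <= res.preserved


def test_preservation_on_synthetic_replicates():
    """Planted-module edges replicate across two independent draws of the
    same generating process."""
    import numpy as np
    import pandas as pd

    mods = (ModuleSpec(6, 0.9),)
    s1, t1 = simulate_study(SimulationConfig(
        n_pairs=50, n_features=40, modules=mods, seed=101))
    s2, t2 = simulate_study(SimulationConfig(
        n_pairs=50, n_features=40, modules=mods, seed=102))
    net1 = build_network(spearman_matrix(s1, tissue="tumour"), alpha=0.05)
    mod1 = sorted(t1.module_members("M1"))
    module_edges = net_from_edges(
        [(a, b, net1.graph[a][b]["rho"])
         for i, a in enumerate(mod1) for b in mod1[i + 1:]
         if net1.graph.has_edge(a, b)])
    # the replicate's module occupies different rows: project its members
    # onto the query's module names before recomputing correlations
    from conftest import make_study
    rep_vals = s2.stratum(tissue="tumour").loc[
        sorted(t2.module_members("M1"))].to_numpy()
    wide = np.repeat(rep_vals, 2, axis=1)  # tissue split is irrelevant here
    ref_study = make_study(wide, n_pairs=rep_vals.shape[1], features=mod1)
    ref_corr = spearman_matrix(ref_study, tissue="tumour")
    res = preservation_vs_reference(module_edges, ref_corr, alpha=0.05)
    assert res.n_query_edges > 0
    assert res.preserved / res.n_query_edges >= 0.8


def test_census_triangle():
    net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
    census = motif_census(net)
    assert census.counts["triangle"] == 1
    assert census.triangles == [("a", "b", "c")]


def test_census_pvac_normal_style_fixture():
    """A 7-node path, two K3s and two K2s (17 nodes): 1 chain, 2
    triangles, 2 pairs."""
    chain = [f"c{i}" for i in range(7)]
    edges = list(zip(chain, chain[1:]))
    edges += [("t1a", "t1b"), ("t1b", "t1c"), ("t1a", "t1c")]
    edges += [("t2a", "t2b"), ("t2b", "t2c"), ("t2a", "t2c")]
    edges += [("p1a", "p1b"), ("p2a", "p2b")]
    net = net_from_edges(edges)
    census = motif_census(net)
    assert census.counts == {"isolated": 0, "pair": 2, "triangle": 2,
                             "chain": 1, "other": 0}
    assert census.n_components == 5
    assert len(census.longest_chain) == 7
    assert census.longest_chain[0] == "c0"


def test_chain_sign_sequence():
    """Sign sequence along the longest chain, e.g. counting consecutive
    inverse correlations."""
    edges = [("a", "b", -0.9), ("b", "c", -0.8), ("c", "d", 0.7),
             ("d", "e", -0.6)]
    census = motif_census(net_from_edges(edges))
    assert census.longest_chain == ["a", "b", "c", "d", "e"]
    assert census.longest_chain_signs == ["inverse", "inverse", "direct",
                                          "inverse"]


def test_component_classes_conserve_component_count(rng):
    for _ in range(10):
        g = random_weighted_graph(rng, n_max=8)
        census = motif_census(g)
        assert census.n_components == nx.number_connected_components(g)


def test_triangle_enumeration_matches_brute_force(rng):
    for _ in range(20):
        g = random_weighted_graph(rng, n_max=8)
        census = motif_census(g)
        assert sorted(census.triangles) == oracles.brute_triangle_list(g)


def test_star_and_tree_are_other_not_chain():
    star = net_from_edges([("h", x) for x in "abc"])
    assert motif_census(star).counts["other"] == 1
    assert motif_census(star).counts["chain"] == 0


def test_neighbourhood_extraction():
    net = net_from_edges([("c", "x", 0.9), ("c", "y", -0.8), ("x", "y"),
                          ("y", "far")], nodes=["c", "x", "y", "far", "iso"])
    nb = neighbourhood(net, "c")
    assert set(nb.neighbours) == {"x", "y"}
    assert nb.neighbours["x"] == (0.9, "direct")
    assert nb.neighbours["y"] == (-0.8, "inverse")
    assert set(nb.graph.nodes()) == {"c", "x", "y"}
    nb2 = neighbourhood(net, "c", radius=2)
    assert "far" in nb2.graph
    iso = neighbourhood(net, "iso")
    assert iso.neighbours == {}
    with pytest.raises(KeyError):
        neighbourhood(net, "missing")


def test_star_neighbourhood_counts_leaves():
    net = net_from_edges([("h", f"l{i}") for i in range(5)])
    assert len(neighbourhood(net, "h").neighbours) == 5
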