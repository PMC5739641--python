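"""MCODE vertex weighting, complex growth, post-processing, density null."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from mirnet.mcode import (McodeParams, mcode_weights, mcode_clusters,
                          cluster_density_pvalue, _haircut, ClusterResult)
from mirnet.simulate import SimulationConfig, ModuleSpec, simulate_study
from mirnet.network import spearman_matrix, build_network
from conftest import net_from_edges, random_weighted_graph
import oracles


def test_isolated_and_low_degree_nodes_score_zero():
    net = net_from_edges([("a", "b")], nodes=["a", "b", "z"])
    w = mcode_weights(net)
    assert w["z"] == 0.0
    assert w["a"] == 0.0  # degree 1 < cutoff 2


def test_clique_member_score_closed_form():
    """Inside K5 the closed neighbourhood is K5 itself: highest core is
    the 4-core with density 1, so the score is 4."""
    g = nx.complete_graph(5)
    w = mcode_weights(g)
    assert all(v == pytest.approx(4.0) for v in w.values())


def test_weights_match_brute_force_subset_enumeration(rng):
    for _ in range(15):
        g = random_weighted_graph(rng, n_max=8)
        w = mcode_weights(g)
        for v in g:
            assert w[v] == pytest.approx(
                oracles.brute_mcode_weight(g, v), abs=1e-12)


def two_k4_with_bridge_and_pendants() -> "CoexpressionNetwork":
    edges = []
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    for grp in (a, b):
        edges += [(x, y) for i, x in enumerate(grp) for y in grp[i + 1:]]
    edges.append(("a0", "b0"))          # bridge between the cliques
    edges += [("a1", "p1"), ("b1", "p2")]  # pendant noise nodes
    return net_from_edges(edges)


def test_two_cliques_hand_traced():
    """Hand-traceable instance: every K4 member scores 3.0 (the 3-core of
    its closed neighbourhood is the K4 itself) and the pendants score 0,
    so growth from the first seed crosses the bridge — both cliques'
    members clear the 0.8 × 3.0 threshold — and the pendants are never
    admitted: one 8-node complex with 13 edges. Without the bridge the
    cliques come out as two separate perfect-density complexes."""
    net = two_k4_with_bridge_and_pendants()
    w = mcode_weights(net)
    assert all(w[v] == pytest.approx(3.0) for v in w if v[0] in "ab")
    assert w["p1"] == w["p2"] == 0.0
    clusters = mcode_clusters(net)
    assert len(clusters) == 1
    assert sorted(clusters[0].members) == [
        "a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3"]
    assert clusters[0].density == pytest.approx(13 / 28)

    bridgeless = two_k4_with_bridge_and_pendants()
    bridgeless.graph.remove_edge("a0", "b0")
    clusters = mcode_clusters(bridgeless)
    assert sorted(sorted(c.members) for c in clusters) == [
        ["a0", "a1", "a2", "a3"], ["b0", "b1", "b2", "b3"]]
    for c in clusters:
        assert c.density == pytest.approx(1.0)
        assert c.seed in c.members


def test_edgeless_network_no_clusters():
    net = net_from_edges([], nodes=["a", "b", "c"])
    assert mcode_clusters(net) == []


def test_haircut_idempotent_and_equals_two_core(rng):
    for _ in range(10):
        g = random_weighted_graph(rng, n_max=8)
        members = set(g.nodes())
        once = _haircut(g, members)
        assert _haircut(g, once) == once
        assert once == set(nx.k_core(g, 2).nodes())


def test_determinism(rng):
    g = random_weighted_graph(rng, n_max=8)
    c1 = mcode_clusters(g)
    c2 = mcode_clusters(g.copy())
    assert [(c.seed, c.members) for c in c1] == \
        [(c.seed, c.members) for c in c2]


def test_clusters_disjoint_and_densities_valid(rng):
    for _ in range(10):
        g = random_weighted_graph(rng, n_max=8)
        clusters = mcode_clusters(g)
        seen = set()
        for c in clusters:
            assert not (c.members & seen)
            seen |= c.members
            assert 0.0 <= c.density <= 1.0
            assert c.size >= 2


def test_planted_module_recovery():
    """Three planted 8-member modules at rho 0.9 among 100 background
    features: MCODE recovers at least 2 with Jaccard ≥ 0.75."""
    cfg = SimulationConfig(
        n_pairs=50, n_features=124, seed=2024,
        modules=tuple(ModuleSpec(8, 0.9) for _ in range(3)))
    study, truth = simulate_study(cfg)
    corr = spearman_matrix(study, tissue="tumour")
    # BH-gated edges: at thousands of pairwise tests the raw-p network
    # drowns the modules in false edges that chain complexes together
    net = build_network(corr, alpha=0.05, bh_correct=True)
    clusters = mcode_clusters(net)
    recovered = 0
    for mid in truth.module_ids:
        mod = truth.module_members(mid)
        best = max((len(mod & c.members) / len(mod | c.members)
                    for c in clusters), default=0.0)
        recovered += best >= 0.75
    assert recovered >= 2


def test_density_pvalue_closed_form_clique():
    """A 5-clique against a background of density 0.1:
    p = P(Bin(10, 0.1) = 10) = 1e-10."""
    g = nx.complete_graph(5)
    cycle = list(range(5, 25))
    g.add_edges_from(zip(cycle, cycle[1:] + cycle[:1]))
    # N=25, E=30 → global density exactly 2·30/(25·24) = 0.1
    assert nx.density(g) == pytest.approx(0.1)
    cluster = ClusterResult(members=frozenset(range(5)), seed=0,
                            density=1.0, score=5.0)
    p = cluster_density_pvalue(cluster, g)
    assert p == pytest.approx(1e-10, rel=1e-6)
    assert p == pytest.approx(stats.binom.sf(9, 10, 0.1))


def test_density_pvalue_null_consistent():
    """A cluster whose density equals the global density is unsurprising."""
    g = nx.gnp_random_graph(30, 0.3, seed=1)
    members = frozenset(list(g.nodes())[:10])
    sub = g.subgraph(members)
    cluster = ClusterResult(members=members, seed=0,
                            density=nx.density(sub), score=1.0)
    assert cluster_density_pvalue(cluster, g) > 0.2


def test_permutation_and_analytic_nulls_cross_validate():
    """Both nulls call a planted clique in a sparse background highly
    significant, and both call a run-of-the-mill subset unsurprising."""
    g = nx.gnp_random_graph(24, 0.08, seed=3)
    clique = list(range(24, 30))
    g.add_edges_from((a, b) for i, a in enumerate(clique)
                     for b in clique[i + 1:])
    c = ClusterResult(members=frozenset(clique), seed=24, density=1.0,
                      score=6.0)
    p_ana = cluster_density_pvalue(c, g, method="analytic")
    p_perm = cluster_density_pvalue(c, g, method="permutation",
                                    n_permutations=199, seed=5)
    assert p_ana < 1e-6
    assert p_perm <= 0.05

    h = nx.gnp_random_graph(24, 0.2, seed=11)
    null_members = frozenset(range(10))
    sub = h.subgraph(null_members)
    c0 = ClusterResult(members=null_members, seed=0,
                       density=nx.density(sub), score=1.0)
    assert cluster_density_pvalue(c0, h, method="analytic") > 0.2
    assert cluster_density_pvalue(c0, h, method="permutation",
                                  n_permutations=99, seed=5) > 0.2


def test_pvalue_requires_two_members():
    g = nx.complete_graph(3)
    c = ClusterResult(members=frozenset([0]), seed=0, density=0, score=0)
    with pytest.raises(ValueError):
        cluster_density_pvalue(c, g)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        McodeParams(degree_cutoff=1).validate()
    with pytest.raises(ValueError):
        McodeParams(node_score_cutoff=1.5).validate()
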