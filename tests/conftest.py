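import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirnet.io import ExpressionStudy
from mirnet.network import CoexpressionNetwork


def make_study(values: np.ndarray, n_pairs: int,
               features: list[str] | None = None,
               cohort: str = "SIM") -> ExpressionStudy:
    """Study with columns S001_N, S001_T, S002_N, ... per subject."""
    n_feat = values.shape[0]
    features = features or [f"miR-{i + 1:03d}" for i in range(n_feat)]
    sample_ids, subj, tissue = [], [], []
    for j in range(n_pairs):
        for t, suf in (("normal", "N"), ("tumour", "T")):
            sample_ids.append(f"S{j + 1:03d}_{suf}")
            subj.append(f"S{j + 1:03d}")
            tissue.append(t)
    return ExpressionStudy(
        pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                     columns=sample_ids),
        pd.DataFrame({"subject_id": subj, "tissue": tissue,
                      "cohort": [cohort] * len(sample_ids)},
                     index=pd.Index(sample_ids, name="sample_id")))


def net_from_edges(edges, nodes=None) -> CoexpressionNetwork:
    """Network from (a, b) or (a, b, rho) tuples; rho defaults to 1."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for e in edges:
        a, b = e[0], e[1]
        rho = float(e[2]) if len(e) > 2 else 1.0
        g.add_edge(a, b, rho=rho, p=0.01,
                   sign="direct" if rho > 0 else "inverse")
    return CoexpressionNetwork(g)


def random_weighted_graph(rng: np.random.Generator, n_max: int = 8,
                          connected: bool = False) -> nx.Graph:
    """Random graph with ≤ n_max nodes and |rho| weights in [0.2, 1)."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.2, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        for a, b in g.edges():
            rho = float(rng.uniform(0.2, 0.999))
            if rng.random() < 0.3:
                rho = -rho
            g[a][b]["rho"] = rho
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
        if not connected or nx.is_connected(g):
            return g


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
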