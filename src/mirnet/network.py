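"""Significance-gated Spearman co-expression networks.

Edges connect miRNA pairs whose Spearman correlation is significant at the
chosen alpha within a sample stratum; each edge carries the correlation
coefficient (the weight), its p-value and a direct/inverse sign. Nodes are
the full supplied miRNA subset, so unconnected miRNAs appear as isolated
nodes.

P-values come from the t-approximation of Spearman's statistic, except in
very small strata (≤ 9 samples by default) where an exact permutation null
is used instead — the t-approximation is unreliable at n as small as 4.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from mirnet.io import ExpressionStudy

logger = logging.getLogger(__name__)

#: strata up to this many samples use the exact permutation p-value
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class CorrelationTable:
    """Symmetric pairwise Spearman table over one sample stratum."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n_samples: int
    stratum: str = ""

    @property
    def features(self) -> list[str]:
        return list(self.rho.index)


@dataclass
class CoexpressionNetwork:
    """Undirected, weighted, sign-annotated co-expression graph.

    Edge attributes: ``rho`` (Spearman coefficient, the weight), ``p``
    and ``sign`` (``direct`` for rho > 0, ``inverse`` for rho < 0).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    stratum: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Edges as lexicographically ordered node pairs."""
        return {tuple(sorted((a, b))) for a, b in self.graph.edges()}

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"a": min(a, b), "b": max(a, b),
             "rho": d.get("rho", np.nan), "p": d.get("p", np.nan),
             "sign": d.get("sign", "")}
            for a, b, d in self.graph.edges(data=True)
        ]
        return (pd.DataFrame(rows, columns=["a", "b", "rho", "p", "sign"])
                .sort_values(["a", "b"]).reset_index(drop=True))

    def write_edgelist(self, path: str | Path) -> None:
        self.to_edge_frame().to_csv(Path(path), sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        g.graph["stratum"] = self.stratum
        nx.write_graphml(g, Path(path))


@lru_cache(maxsize=4)
def _permutation_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


@lru_cache(maxsize=4)
def _tie_free_null(n: int) -> np.ndarray:
    """Null |rho| values over all permutations of tie-free ranks."""
    ranks = np.arange(1, n + 1, dtype=float)
    perms = ranks[_permutation_indices(n)]
    c = ranks - ranks.mean()
    pc = perms - ranks.mean()
    denom = np.sqrt((c ** 2).sum()) * np.sqrt((pc ** 2).sum(axis=1))
    return np.abs(pc @ c) / denom


def _exact_p(rank_x: np.ndarray, rank_y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    With tie-free ranks the null depends only on n and a cached table is
    used; with midranks the permutation distribution is computed for the
    pair at hand.
    """
    n = len(rank_x)
    tol = 1e-12
    tie_free = (len(np.unique(rank_x)) == n and len(np.unique(rank_y)) == n)
    if tie_free:
        null = _tie_free_null(n)
    else:
        perms = rank_y[_permutation_indices(n)]
        cx = rank_x - rank_x.mean()
        cy = perms - rank_y.mean()
        sx = np.sqrt((cx ** 2).sum())
        sy = np.sqrt((cy ** 2).sum(axis=1))
        null = np.abs(cy @ cx) / (sx * sy)
    return float(np.mean(null >= abs(rho) - tol))


def _tapprox_p(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0 - 1e-15, 0.0, p)
    return p


def spearman_matrix(study: ExpressionStudy,
                    features: list[str] | None = None,
                    tissue: str | None = None,
                    cohort: str | None = None,
                    method: str = "auto") -> CorrelationTable:
    """Pairwise Spearman correlations within a sample stratum.

    Ties are handled with midranks. ``method`` selects the p-value route:
    ``"auto"`` (exact permutation when the stratum has ≤ 9 samples, else
    the two-sided t-approximation), ``"exact"`` or ``"tapprox"``.
    Constant features get rho 0 and p 1 against every partner, with a
    warning.
    """
    if method not in ("auto", "exact", "tapprox"):
        raise ValueError(f"unknown method {method!r}")
    sub = study.stratum(tissue=tissue, cohort=cohort)
    if features is not None:
        missing = [f for f in features if f not in sub.index]
        if missing:
            raise KeyError(f"feature(s) not in study: {missing[:5]}")
        sub = sub.loc[features]
    n = sub.shape[1]
    if n < 3:
        raise ValueError(f"need ≥ 3 samples in stratum, got {n}")
    X = sub.to_numpy(dtype=float)
    ranks = stats.rankdata(X, axis=1)
    constant = ranks.std(axis=1) == 0
    if constant.any():
        logger.warning("%d constant feature(s) in stratum; rho set to 0, "
                       "p to 1", int(constant.sum()))

    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.where(np.isnan(rho), 0.0, rho)
    np.fill_diagonal(rho, 1.0)

    use_exact = method == "exact" or (
        method == "auto" and n <= EXACT_PERMUTATION_MAX_N)
    if use_exact:
        m = X.shape[0]
        p = np.ones((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                if constant[i] or constant[j]:
                    continue
                p[i, j] = p[j, i] = _exact_p(ranks[i], ranks[j],
                                             float(rho[i, j]))
    else:
        p = _tapprox_p(rho, n)
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)

    idx = pd.Index(sub.index, name="feature_id")
    label = "/".join(x for x in (cohort, tissue) if x) or "all"
    return CorrelationTable(pd.DataFrame(rho, index=idx, columns=idx),
                            pd.DataFrame(p, index=idx, columns=idx),
                            n_samples=n, stratum=label)


def build_network(corr: CorrelationTable,
                  features: list[str] | None = None,
                  alpha: float = 0.05,
                  bh_correct: bool = False) -> CoexpressionNetwork:
    """Threshold a correlation table into a co-expression graph.

    An edge joins every pair with correlation p < ``alpha`` (optionally
    after Benjamini–Hochberg adjustment of the upper-triangle p-values
    when ``bh_correct`` is set). The node set is the full feature subset,
    including isolated miRNAs.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    feats = features if features is not None else corr.features
    missing = [f for f in feats if f not in corr.rho.index]
    if missing:
        raise KeyError(f"feature(s) not in correlation table: {missing[:5]}")
    rho = corr.rho.loc[feats, feats].to_numpy()
    p = corr.p.loc[feats, feats].to_numpy()
    m = len(feats)
    iu, ju = np.triu_indices(m, k=1)
    pvals = p[iu, ju]
    if bh_correct and len(pvals):
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]

    g = nx.Graph()
    g.add_nodes_from(feats)
    for i, j, pv in zip(iu, ju, pvals):
        r = float(rho[i, j])
        if pv < alpha and r != 0.0:
            a, b = feats[i], feats[j]
            g.add_edge(a, b, rho=r, p=float(pv),
                       sign="direct" if r > 0 else "inverse")
    return CoexpressionNetwork(g, stratum=corr.stratum)


def read_graphml(path: str | Path) -> CoexpressionNetwork:
    g = nx.read_graphml(Path(path))
    return CoexpressionNetwork(nx.Graph(g),
                               stratum=str(g.graph.get("stratum", "")))
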