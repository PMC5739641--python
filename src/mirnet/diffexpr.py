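"""Paired differential expression with signed fold-changes and FDR control.

Each miRNA is tested with a paired t-test on the within-subject
tumour − normal log2 differences; Benjamini–Hochberg q-values are computed
over all tested features. Fold-changes use the sign-encoded linear
convention common in microarray tables: a value of −1.5 means 1.5-fold
down in tumour, so no value ever falls strictly inside (−1, 1).

Selection defaults to the raw p-value at alpha = 0.05 (the convention of
the tables this mirrors); the stricter q-value gate is available via
``use_q=True``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirnet.io import ExpressionStudy

logger = logging.getLogger(__name__)


def encode_signed_fc(mean_log2_diff: float) -> float:
    """Map a log2 difference to the signed linear fold-change convention.

    ``m ≥ 0 → 2**m`` (up in tumour), ``m < 0 → −2**(−m)`` (down), so the
    magnitude is always ≥ 1 and ``encode(0) = 1``.
    """
    if mean_log2_diff >= 0:
        return float(2.0 ** mean_log2_diff)
    return float(-(2.0 ** (-mean_log2_diff)))


def decode_signed_fc(signed_fc: float) -> float:
    """Inverse of :func:`encode_signed_fc`."""
    if abs(signed_fc) < 1.0:
        raise ValueError(
            f"signed fold-change magnitude must be ≥ 1, got {signed_fc}")
    if signed_fc >= 1.0:
        return math.log2(signed_fc)
    return -math.log2(-signed_fc)


@dataclass(frozen=True)
class DiffExprRecord:
    mirna: str
    signed_fc: float
    mean_log2_diff: float
    t_stat: float
    p_value: float
    q_value: float


def _records_from_diffs(features, diffs: np.ndarray, t: np.ndarray,
                        p: np.ndarray) -> list[DiffExprRecord]:
    q = multipletests(p, method="fdr_bh")[1]
    mean_diff = diffs
    return [
        DiffExprRecord(mirna=f,
                       signed_fc=encode_signed_fc(float(m)),
                       mean_log2_diff=float(m),
                       t_stat=float(ti),
                       p_value=float(pi),
                       q_value=float(qi))
        for f, m, ti, pi, qi in zip(features, mean_diff, t, p, q)
    ]


def paired_ttest(study: ExpressionStudy,
                 cohort: str | None = None) -> list[DiffExprRecord]:
    """Paired t-test per miRNA on tumour − normal log2 differences.

    Uses the Student t distribution with ``n_pairs − 1`` degrees of
    freedom. Features whose differences have zero variance are reported
    with p = 1 (t undefined) and a warning. Records are returned in the
    study's feature order and are sortable by ``p_value``.
    """
    diffs = study.paired_differences(cohort=cohort)
    n = diffs.shape[1]
    if n < 2:
        raise ValueError(f"paired t-test needs ≥ 2 complete pairs, got {n}")
    d = diffs.to_numpy()
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    t = np.zeros_like(mean)
    p = np.ones_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / math.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    t[~ok] = np.nan
    if (~ok).any():
        logger.warning("%d feature(s) with zero-variance differences; "
                       "t undefined, p set to 1", int((~ok).sum()))
    return _records_from_diffs(diffs.index, mean, t, p)


def select_deregulated(records: list[DiffExprRecord], alpha: float = 0.05,
                       use_q: bool = False) -> set[str]:
    """miRNAs significant at ``alpha`` (raw p by default, q if ``use_q``)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    key = (lambda r: r.q_value) if use_q else (lambda r: r.p_value)
    return {r.mirna for r in records if key(r) < alpha}


def cross_cohort_contrast(study_a: ExpressionStudy,
                          study_b: ExpressionStudy
                          ) -> list[DiffExprRecord]:
    """Contrast the paired tumour − normal differences of two cohorts.

    Per feature, a Welch (unequal-variance) two-sample t-test compares the
    subject-level paired log2 differences of cohort A against cohort B;
    the signed fold-change encodes the ratio of the two cohorts' linear
    fold-changes (mean difference of log2 differences). Only features
    shared by both studies are tested.
    """
    shared = [f for f in study_a.features if f in set(study_b.features)]
    if not shared:
        raise ValueError("no shared features between cohorts")
    da = study_a.paired_differences().loc[shared].to_numpy()
    db = study_b.paired_differences().loc[shared].to_numpy()
    if da.shape[1] < 2 or db.shape[1] < 2:
        raise ValueError("each cohort needs ≥ 2 complete pairs")
    t, p = stats.ttest_ind(da, db, axis=1, equal_var=False)
    mean = da.mean(axis=1) - db.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    return _records_from_diffs(shared, mean, t, p)


def records_to_frame(records: list[DiffExprRecord]):
    """Tabulate records (one row per miRNA) sorted by p-value."""
    import pandas as pd

    df = pd.DataFrame([r.__dict__ for r in records])
    return df.sort_values(["p_value", "mirna"]).reset_index(drop=True)
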