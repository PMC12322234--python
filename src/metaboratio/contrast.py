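"""Two-cluster feature-wise contrasts with adaptive FDR control.

Each feature is tested with an unpaired equal-variance Student's t-test
(Welch available behind a flag); the family of p-values is corrected with
the Benjamini-Krieger-Yekutieli two-stage linear step-up procedure at a
target FDR of 5% by default.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def student_t(a, b, welch: bool = False) -> TTestResult:
    """Unpaired t-test: pooled-variance Student's t by default.

    df = len(a) + len(b) - 2 for the pooled test; two-sided p.  When both
    groups are constant and identical the 0/0 statistic is defined as
    t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # zero variance in both groups
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:  # infinite evidence of a difference
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    return TTestResult(t=t, df=df, p=p)


def bky_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Krieger-Yekutieli two-stage adaptive linear step-up.

    Stage 1 runs BH at q' = q / (1 + q), yielding r1 rejections and the
    estimate m0 = m - r1 of the number of true nulls; stage 2 reruns the
    step-up with slope q' * i / m0.  r1 in {0, m} short-circuits to
    rejecting none / all.  Adjusted q-values are defined consistently with
    the final threshold, so ``reject[i] == (qvals[i] <= q)``.

    Returns (reject boolean array, adjusted q array), in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    q1 = q / (1.0 + q)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)

    def _stepup_count(slope_per_rank: np.ndarray) -> int:
        passed = np.flatnonzero(ps <= slope_per_rank)
        return int(passed[-1] + 1) if len(passed) else 0

    r1 = _stepup_count(q1 * ranks / m)
    if r1 == 0:
        m0 = m
        n_reject = 0
    elif r1 == m:
        m0 = m
        n_reject = m
    else:
        m0 = m - r1
        n_reject = _stepup_count(q1 * ranks / m0)
    # adjusted q: monotone step-up envelope of p * m0 * (1 + q) / rank
    raw = ps * m0 * (1.0 + q) / ranks
    qs = np.minimum.accumulate(raw[::-1])[::-1]
    np.clip(qs, 0.0, 1.0, out=qs)
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:n_reject] = True
    reject = np.empty(m, dtype=bool)
    qvals = np.empty(m)
    reject[order] = reject_sorted
    qvals[order] = qs
    return reject, qvals


def contrast_clusters(
    features: pd.DataFrame,
    labels: pd.Series,
    cluster_a,
    cluster_b,
    q: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Feature-wise contrast of two clusters with BKY FDR across all features.

    ``features`` is samples x features; ``labels`` maps sample id ->
    cluster.  Constant features are kept as t = 0, p = 1 rows, never
    dropped, so the FDR family stays the full panel.
    """
    members_a = labels.index[labels == cluster_a]
    members_b = labels.index[labels == cluster_b]
    if len(members_a) < 2 or len(members_b) < 2:
        raise ValueError(
            f"both clusters need >=2 members (got {len(members_a)} and {len(members_b)})"
        )
    A = features.loc[members_a]
    B = features.loc[members_b]
    rows = []
    for feat in features.columns:
        t, df, pval = student_t(A[feat].to_numpy(), B[feat].to_numpy(), welch=welch)
        rows.append(
            {
                "feature": feat,
                "mean_a": float(A[feat].mean()),
                "mean_b": float(B[feat].mean()),
                "diff": float(A[feat].mean() - B[feat].mean()),
                "t": t,
                "df": df,
                "p": pval,
            }
        )
    table = pd.DataFrame(rows)
    reject, qvals = bky_fdr(table["p"].to_numpy(), q=q)
    table["q"] = qvals
    table["reject"] = reject
    return table
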