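"""Per-gene statistics and QC for sex-stratified expression matrices.

Covariate-free throughout, for consistency with the network comparison:
pooled-variance two-sample t-tests for differential expression, variance
ratio F-tests for differential variability, Benjamini-Hochberg FDR, and
a marker-gene PCA check that flags recorded-sex/cluster mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1.  NaN p-values
    propagate to NaN q-values and are excluded from the correction.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def pooled_ttest(a: np.ndarray, b: np.ndarray, axis: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized unpaired two-sample t-test with pooled variance.

    Rows (entities) are tested independently across the given axis.
    Degenerate rows where both groups have zero variance get t = 0 and
    p = 1 when the means agree, and +/-inf, p = 0 when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[axis], b.shape[axis]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 observations")
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va, vb = a.var(axis=axis, ddof=1), b.var(axis=axis, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0, np.sign(diff) * np.inf, t)
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, p


def _split_groups(values: pd.DataFrame, groups: Sequence) -> tuple[str, str, np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    if groups.shape[0] != values.shape[1]:
        raise ValueError("group labels must align with sample columns")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    a, b = levels
    return a, b, values.loc[:, groups == a].to_numpy(), values.loc[:, groups == b].to_numpy()


def differential_expression_ttest(values: pd.DataFrame, groups: Sequence) -> pd.DataFrame:
    """Per-gene pooled two-sample t-test between the two group levels.

    Levels are compared in sorted order (so F - M for sex labels).
    Returns a gene-indexed table with group means, t, p and BH q.
    """
    a, b, xa, xb = _split_groups(values, groups)
    t, p = pooled_ttest(xa, xb)
    if (np.asarray(p) == 1.0).any() and ((xa.var(axis=1) == 0) & (xb.var(axis=1) == 0)).any():
        warnings.warn("genes with zero variance in both groups: p set to 1",
                      stacklevel=2)
    return pd.DataFrame({
        f"mean_{a}": xa.mean(axis=1),
        f"mean_{b}": xb.mean(axis=1),
        "statistic": t,
        "p_value": p,
        "fdr_q": bh_fdr(p),
    }, index=values.index)


def differential_variance_ftest(values: pd.DataFrame, groups: Sequence) -> pd.DataFrame:
    """Two-sided variance-ratio F-test per gene.

    F = s2_a / s2_b with (n_a - 1, n_b - 1) degrees of freedom and
    two-sided p = 2 * min(tail, 1 - tail).  Zero variance in the
    denominator group yields p = NaN with a warning.
    """
    a, b, xa, xb = _split_groups(values, groups)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 3 or nb < 3:
        raise ValueError("each group needs >= 3 observations for the F-test")
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = va / vb
    bad = vb == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} genes with zero denominator variance: p = NaN",
                      stacklevel=2)
    cdf = stats.f.cdf(f, na - 1, nb - 1)
    p = 2.0 * np.minimum(cdf, 1.0 - cdf)
    p = np.minimum(p, 1.0)
    p[bad] = np.nan
    f = np.where(bad, np.nan, f)
    return pd.DataFrame({
        f"var_{a}": va,
        f"var_{b}": vb,
        "statistic": f,
        "p_value": p,
        "fdr_q": bh_fdr(p),
    }, index=values.index)


@dataclass
class SexCheckResult:
    scores: pd.DataFrame          # samples x (PC1, PC2)
    flagged: list[str]            # sample ids whose recorded sex disagrees
    cluster: pd.Series            # cluster assignment on PC1


def _kmeans_1d(x: np.ndarray) -> np.ndarray:
    """Exact 2-means in one dimension via the best sorted split."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    csum = np.cumsum(xs)
    total = csum[-1]
    best_cost, best_split = np.inf, 1
    for k in range(1, n):
        m1 = csum[k - 1] / k
        m2 = (total - csum[k - 1]) / (n - k)
        cost = (np.sum((xs[:k] - m1) ** 2) + np.sum((xs[k:] - m2) ** 2))
        if cost < best_cost:
            best_cost, best_split = cost, k
    labels = np.zeros(n, dtype=int)
    labels[order[best_split:]] = 1
    return labels


def sex_check_pca(values: pd.DataFrame, marker_genes: Sequence[str],
                  recorded_sex: Sequence) -> SexCheckResult:
    """PCA on sex-marker genes; flag samples clustering with the wrong sex.

    Principal components of the gene-centered marker submatrix (samples
    as observations) are computed; samples are split into two groups by
    exact 2-means on PC1 and flagged when their recorded sex differs
    from the majority recorded sex of their cluster.
    """
    present = [g for g in marker_genes if g in values.index]
    if len(present) < 2:
        raise ValueError("need >= 2 marker genes present in the matrix")
    sub = values.loc[present].to_numpy().T  # samples x markers
    centered = sub - sub.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("markers uninformative (all constant)")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pcs = u * s
    scores = pd.DataFrame(pcs[:, :2], index=values.columns, columns=["PC1", "PC2"])
    labels = _kmeans_1d(pcs[:, 0])
    sex = pd.Series(np.asarray(recorded_sex), index=values.columns)
    flagged = []
    cl = pd.Series(labels, index=values.columns)
    for lab in (0, 1):
        members = cl.index[cl == lab]
        if len(members) == 0:
            continue
        majority = sex.loc[members].mode().iloc[0]
        flagged.extend(m for m in members if sex.loc[m] != majority)
    return SexCheckResult(scores=scores, flagged=sorted(flagged), cluster=cl)
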