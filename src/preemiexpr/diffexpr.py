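"""Univariate differential-expression screens.

Three screens are provided, each returning a per-gene result table with
FDR control and fold-change annotation:

* :func:`correlate_oxygen` — Spearman rank correlation of normalized
  expression with cumulative oxygen utilization (Oxygen_AUC14), restricted
  upstream to the extremely preterm (<29 wk) subgroup.
* :func:`samseq_test` — a SAM-Seq-style two-group test on raw counts:
  Poisson down-sampling of every subject to the minimum sequencing depth,
  Wilcoxon rank-sum z averaged over resamples, label-permutation null and a
  median-FDR (mFDR) estimate.
* :func:`lrt_adjusted` — per-gene logistic likelihood-ratio test of the
  outcome on expression, adjusted for gestational age at birth.

Thresholds default to 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import batched_feature_lrt
from .matrix import CountMatrix, NormalizedMatrix

DEFAULT_FDR = 0.1

DE_COLUMNS = [
    "gene_id", "statistic", "p_value", "q_value",
    "log2_fold_change", "direction", "significant",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adjusted, 1.0)
    return q


# --------------------------------------------------------------- rank utils

def spearman_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho of X (G x n) against y, with t-approximation p-values.

    Midranks throughout; rho is the Pearson correlation of the ranks.
    """
    G, n = X.shape
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return rho, p


def tie_term(ranks: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row, from a matrix of midranks.

    Midranks are integer multiples of 1/2, so doubling gives exact integers
    and run lengths can be found in one flat pass over all rows.
    """
    G, n = ranks.shape
    as_int = np.sort(np.round(ranks * 2).astype(np.int64), axis=1)
    flat = (as_int + (np.arange(G, dtype=np.int64) * (2 * n + 2))[:, None]).ravel()
    change = np.ones(flat.size, dtype=bool)
    change[1:] = flat[1:] != flat[:-1]
    starts = np.nonzero(change)[0]
    lengths = np.diff(np.append(starts, flat.size)).astype(float)
    rows = starts // n
    return np.bincount(rows, weights=lengths ** 3 - lengths, minlength=G)


def ranksum_sigma(ranks: np.ndarray, n1: int) -> np.ndarray:
    """Tie-corrected null SD of the group-1 rank sum, per row of midranks."""
    G, n = ranks.shape
    n0 = n - n1
    var = (n1 * n0 / 12.0) * ((n + 1) - tie_term(ranks) / (n * (n - 1)))
    return np.sqrt(np.maximum(var, 0.0))


def ranksum_z(values: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Tie-corrected standardized Wilcoxon rank-sum statistic per row.

    ``group`` is a boolean vector marking the case group; z > 0 means higher
    ranks (higher expression) in cases.
    """
    G, n = values.shape
    n1 = int(group.sum())
    ranks = stats.rankdata(values, axis=1)
    w = ranks @ group.astype(float)
    mu = n1 * (n + 1) / 2.0
    sigma = ranksum_sigma(ranks, n1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - mu) / sigma
    return np.nan_to_num(z, nan=0.0)


def exact_ranksum_pmf(n1: int, n0: int) -> np.ndarray:
    """Exact null pmf of the Mann–Whitney U statistic (no ties).

    Counting recurrence on the largest observation: N(i, j, u) =
    N(i-1, j, u-j) + N(i, j-1, u), with group sizes (i, j).
    """
    max_u = n1 * n0
    prev = [np.zeros(max_u + 1) for _ in range(n0 + 1)]
    for j in range(n0 + 1):
        prev[j][0] = 1.0
    for _ in range(n1):
        cur = [np.zeros(max_u + 1) for _ in range(n0 + 1)]
        cur[0][0] = 1.0
        for j in range(1, n0 + 1):
            cur[j][:] = cur[j - 1]
            cur[j][j:] += prev[j][: max_u + 1 - j]
        prev = cur
    pmf = prev[n0]
    return pmf / pmf.sum()


def exact_ranksum_p(u: float, n1: int, n0: int) -> float:
    """Two-sided exact Mann–Whitney p-value (no ties): P(|U - n1*n0/2| >= observed)."""
    pmf = exact_ranksum_pmf(n1, n0)
    center = n1 * n0 / 2.0
    dev = abs(u - center)
    support = np.arange(n1 * n0 + 1)
    return float(pmf[np.abs(support - center) >= dev - 1e-9].sum())


def median_log2_fold_change(values: np.ndarray, group: np.ndarray,
                            pseudo: float = 1.0) -> np.ndarray:
    """log2 of the case/control ratio of per-group medians (plus a pseudocount)."""
    med1 = np.median(values[:, group], axis=1)
    med0 = np.median(values[:, ~group], axis=1)
    return np.log2((med1 + pseudo) / (med0 + pseudo))


# ------------------------------------------------------------------ screens

def correlate_oxygen(norm: NormalizedMatrix, auc: pd.Series,
                     fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Spearman correlation of each gene's log2 expression with Oxygen_AUC14.

    Fold changes are annotated between the high- and low-exposure halves
    (AUC above vs at-or-below the median); ``direction`` follows the fold
    change so the two always agree in sign.
    """
    auc = auc.loc[norm.subject_ids]
    y = auc.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("oxygen AUC vector is constant; correlation undefined")
    X = norm.log2_values.to_numpy()
    rho, p = spearman_matrix(X, y)
    q = bh_fdr(p)
    high = y > np.median(y)
    lfc = median_log2_fold_change(norm.pre_log.to_numpy(), high)
    return pd.DataFrame({
        "gene_id": norm.gene_ids,
        "statistic": rho,
        "p_value": p,
        "q_value": q,
        "log2_fold_change": lfc,
        "direction": np.where(lfc >= 0, "up", "down"),
        "significant": q < fdr,
    }).sort_values("q_value", kind="mergesort").reset_index(drop=True)


def samseq_test(counts: CountMatrix, group, n_resamples: int = 20,
                n_perms: int = 1000, seed: int = 0,
                fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """SAM-Seq-style resampling Wilcoxon test on raw counts.

    Every subject is Poisson down-sampled to the minimum sequencing depth
    (neutralizing depth differences), the tie-corrected rank-sum z is
    averaged over resamples, and significance is judged against a
    label-permutation null via the median FDR: for each threshold, the
    median (over permutations) count of null exceedances divided by the
    observed call count, made monotone step-up.
    """
    group = np.asarray(group, dtype=bool)
    values = counts.counts.to_numpy()
    G, n = values.shape
    if group.size != n:
        raise ValueError("group labels must align with subjects")
    if group.sum() < 3 or (~group).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    rng = np.random.default_rng(seed)
    depths = values.sum(axis=0).astype(float)
    scale = depths.min() / depths
    equal_depth = np.allclose(scale, 1.0)
    if equal_depth:
        n_resamples = 1  # nothing to equalize; resampling would only add noise

    perm_matrix = np.empty((n, n_perms))
    for b in range(n_perms):
        perm_matrix[:, b] = rng.permutation(group).astype(float)

    n1 = int(group.sum())
    n0 = n - n1
    mu = n1 * (n + 1) / 2.0
    acc_obs = np.zeros(G)
    acc_null = np.zeros((G, n_perms))
    for _ in range(n_resamples):
        ds = values if equal_depth else rng.poisson(values * scale[None, :])
        ranks = stats.rankdata(ds, axis=1)
        sigma = np.maximum(ranksum_sigma(ranks, n1), 1e-12)
        acc_obs += (ranks @ group.astype(float) - mu) / sigma
        acc_null += (ranks @ perm_matrix - mu) / sigma[:, None]
    d_obs = acc_obs / n_resamples
    d_null = acc_null / n_resamples

    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="mergesort")
    thresholds = abs_obs[order]
    null_sorted = np.sort(np.abs(d_null), axis=0)
    exceed = G - np.apply_along_axis(
        np.searchsorted, 0, null_sorted, thresholds, side="left")
    med_exceed = np.median(exceed, axis=1)
    calls = np.arange(1, G + 1, dtype=float)
    mfdr_sorted = np.minimum.accumulate((med_exceed / calls)[::-1])[::-1]
    mfdr = np.empty(G)
    mfdr[order] = np.minimum(mfdr_sorted, 1.0)

    pooled_null = np.sort(np.abs(d_null).ravel())
    p_perm = 1.0 - np.searchsorted(pooled_null, abs_obs, side="left") / pooled_null.size

    norm_counts = values / depths[None, :] * depths.mean()
    lfc = median_log2_fold_change(norm_counts, group)
    return pd.DataFrame({
        "gene_id": counts.gene_ids,
        "statistic": d_obs,
        "p_value": p_perm,
        "q_value": mfdr,
        "log2_fold_change": lfc,
        "direction": np.where(lfc >= 0, "up", "down"),
        "significant": mfdr < fdr,
    }).sort_values("q_value", kind="mergesort").reset_index(drop=True)


def lrt_adjusted(norm: NormalizedMatrix, outcome, gab_weeks,
                 fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Per-gene GAB-adjusted logistic likelihood-ratio test.

    Null: outcome ~ GAB; full: outcome ~ GAB + log2 expression.  Perfect
    separation falls back to a small ridge penalty, flagged per gene in the
    ``penalized`` column.
    """
    y = np.asarray(outcome, dtype=float)
    gab = np.asarray(gab_weeks, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome does not vary")
    X = norm.log2_values.to_numpy()
    covariates = None if np.ptp(gab) == 0 else gab
    stat, p, penalized = batched_feature_lrt(X, y, covariates)
    q = bh_fdr(p)
    lfc = median_log2_fold_change(norm.pre_log.to_numpy(), y.astype(bool))
    return pd.DataFrame({
        "gene_id": norm.gene_ids,
        "statistic": stat,
        "p_value": p,
        "q_value": q,
        "log2_fold_change": lfc,
        "direction": np.where(lfc >= 0, "up", "down"),
        "significant": q < fdr,
        "penalized": penalized,
    }).sort_values("q_value", kind="mergesort").reset_index(drop=True)
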