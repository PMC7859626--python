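"""Screened principal components (sPCA) classifier for BPD.

Pipeline: univariate Wilcoxon screen of genes at a p-value threshold chosen
by inner cross-validation, PC1 of the surviving genes (near-zero loadings
pruned and the component refit), then a logistic model of the outcome on
the PC1 score (optionally with gestational age at birth).  ROC/AUC are
reported both naively (in-sample, on the full-data refit) and honestly via
an outer loop of nested cross-validation in which every selection step is
rerun inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from ._glm import fit_logistic
from .diffexpr import exact_ranksum_p, ranksum_sigma, ranksum_z
from .matrix import NormalizedMatrix

DEFAULT_ALPHA_GRID = (0.001, 0.005, 0.01, 0.05, 0.10)


# ------------------------------------------------------------------ screen

def wilcoxon_screen(norm: NormalizedMatrix, outcome, alpha: float = 0.10,
                    gab_weeks=None) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum screen; survivors at p < alpha, ascending p.

    Midrank normal approximation with continuity correction for n > 25;
    exact enumeration at small n when a gene has no ties.  With
    ``gab_weeks`` given, gene ranks are residualized on GAB ranks and
    re-ranked before testing (rank-based partial association).
    """
    y = np.asarray(outcome, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be non-empty")
    X = norm.log2_values.to_numpy()
    p = _wilcoxon_pvalues(X, y, gab_weeks)
    out = pd.DataFrame({"gene_id": norm.gene_ids, "p_value": p})
    out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    out["survives"] = out["p_value"] < alpha
    return out


def _wilcoxon_pvalues(X: np.ndarray, y: np.ndarray, gab_weeks=None) -> np.ndarray:
    G, n = X.shape
    if gab_weeks is not None:
        rg = stats.rankdata(np.asarray(gab_weeks, dtype=float))
        rg = (rg - rg.mean())
        rg_norm = rg / ((rg ** 2).sum() or 1.0)
        rx = stats.rankdata(X, axis=1)
        resid = rx - np.outer(rx @ rg_norm, rg) - rx.mean(axis=1, keepdims=True)
        X = stats.rankdata(resid, axis=1)
    n1 = int(y.sum())
    n0 = n - n1
    if n > 25:
        ranks = stats.rankdata(X, axis=1)
        w = ranks @ y.astype(float)
        mu = n1 * (n + 1) / 2.0
        sigma = ranksum_sigma(ranks, n1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zc = np.maximum(np.abs(w - mu) - 0.5, 0.0) / sigma
        zc = np.nan_to_num(zc, nan=0.0, posinf=np.inf)
        return 2.0 * stats.norm.sf(zc)
    p = np.empty(G)
    for g in range(G):
        row = X[g]
        if np.unique(row).size < n:  # ties: midrank normal approximation
            z = ranksum_z(row[None, :], y)[0]
            p[g] = 2.0 * stats.norm.sf(abs(z))
        else:
            ranks = stats.rankdata(row)
            u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
            p[g] = exact_ranksum_p(u, n1, n0)
    return np.minimum(p, 1.0)


# --------------------------------------------------------------------- PCA

@dataclass
class PCResult:
    loadings: pd.Series          # unit vector over retained genes
    scores: pd.Series            # per-subject PC1 score
    gene_means: pd.Series
    gene_scales: pd.Series

    def project(self, log2_values: pd.DataFrame) -> pd.Series:
        x = log2_values.loc[self.loadings.index].to_numpy()
        x = (x - self.gene_means.to_numpy()[:, None]) / self.gene_scales.to_numpy()[:, None]
        return pd.Series(x.T @ self.loadings.to_numpy(), index=log2_values.columns)


def _leading_right_singular(xs: np.ndarray) -> np.ndarray:
    # xs: subjects x genes, centered/scaled; returns gene loading vector
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    return vt[0]


def _fix_sign(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s > 0:
        return v
    if s < 0:
        return -v
    nz = v[v != 0]
    return v if (nz.size == 0 or nz[0] > 0) else -v


def pc1_fit(submatrix: pd.DataFrame, prune_frac: float = 0.1,
            scale: bool = True) -> PCResult:
    """PC1 of a genes x subjects submatrix with one prune-and-refit pass.

    Genes are centered (and by default scaled to unit variance); genes with
    |loading| < prune_frac * max|loading| are dropped and PC1 recomputed on
    the survivors.  Sign convention: sum of loadings positive (first
    non-zero loading positive on an exact tie).
    """
    if submatrix.shape[0] < 1:
        raise ValueError("need at least one gene")
    means = submatrix.mean(axis=1)
    if scale:
        scales = submatrix.std(axis=1, ddof=1).replace(0.0, np.nan)
    else:
        scales = pd.Series(1.0, index=submatrix.index)
    keep = scales.notna() if scale else (submatrix.std(axis=1, ddof=1) > 0)
    if not keep.any():
        raise ValueError("all genes constant; PC1 undefined")
    sub = submatrix.loc[keep]
    means, scales = means.loc[keep], scales.loc[keep].fillna(1.0)
    xs = ((sub.to_numpy() - means.to_numpy()[:, None]) / scales.to_numpy()[:, None]).T
    v = _leading_right_singular(xs)
    if prune_frac > 0 and len(v) > 1:
        mask = np.abs(v) >= prune_frac * np.abs(v).max()
        if mask.sum() < len(v):
            sub, means, scales = sub.loc[mask], means.loc[mask], scales.loc[mask]
            xs = xs[:, mask]
            v = _leading_right_singular(xs)
    v = _fix_sign(v / np.linalg.norm(v))
    loadings = pd.Series(v, index=sub.index)
    scores = pd.Series(xs @ v, index=submatrix.columns)
    return PCResult(loadings, scores, means, scales)


# ------------------------------------------------------------------ models

@dataclass
class ScreenedPCModel:
    screen_threshold: float
    screened_genes: list[str]
    pc: PCResult
    logistic_coefficients: dict[str, float]
    include_gab: bool
    seed: int
    inner_cv_auc: pd.Series = field(default=None, repr=False)

    def predict_proba(self, log2_values: pd.DataFrame, gab_weeks=None) -> pd.Series:
        score = self.pc.project(log2_values)
        eta = (self.logistic_coefficients["intercept"]
               + self.logistic_coefficients["pc1"] * score.to_numpy())
        if self.include_gab:
            eta = eta + self.logistic_coefficients["gab"] * np.asarray(gab_weeks, float)
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=log2_values.columns)

    def to_dict(self) -> dict:
        return {
            "screen_threshold": self.screen_threshold,
            "screened_genes": self.screened_genes,
            "pc1_loadings": self.pc.loadings.to_dict(),
            "logistic_coefficients": self.logistic_coefficients,
            "include_gab": self.include_gab,
            "seed": self.seed,
        }


@dataclass
class RocResult:
    points: pd.DataFrame         # threshold, sensitivity, specificity
    naive_auc: float
    cv_auc: float
    fold_assignments: pd.Series
    seed: int
    heldout_probs: pd.Series = field(default=None, repr=False)
    baseline: "RocResult | None" = None


def _fit_logistic_model(score: np.ndarray, y: np.ndarray, gab=None) -> dict[str, float]:
    cols = [np.ones_like(score), score]
    if gab is not None:
        cols.append(np.asarray(gab, dtype=float))
    X = np.column_stack(cols)
    beta, _, conv = fit_logistic(X, y.astype(float))
    if not conv:
        beta, _, _ = fit_logistic(X, y.astype(float), ridge=1e-3)
    out = {"intercept": float(beta[0]), "pc1": float(beta[1])}
    if gab is not None:
        out["gab"] = float(beta[2])
    return out


def _fit_predict_alpha(train_norm, y_train, gab_train, test_log2, gab_test,
                       pvals: np.ndarray, alpha: float, prune_frac: float,
                       scale: bool):
    mask = pvals < alpha
    if not mask.any():
        return np.full(test_log2.shape[1], 0.5)
    genes = np.asarray(train_norm.gene_ids)[mask]
    pc = pc1_fit(train_norm.log2_values.loc[genes], prune_frac, scale)
    coef = _fit_logistic_model(pc.scores.to_numpy(), y_train, gab_train)
    score = pc.project(test_log2).to_numpy()
    eta = coef["intercept"] + coef["pc1"] * score
    if gab_test is not None:
        eta = eta + coef["gab"] * np.asarray(gab_test, float)
    return 1.0 / (1.0 + np.exp(-eta))


def fit_spca_classifier(norm: NormalizedMatrix, outcome, gab_weeks=None,
                        alpha_grid=DEFAULT_ALPHA_GRID, cv_folds: int = 10,
                        cv_repeats: int = 3, include_gab: bool = False,
                        prune_frac: float = 0.1, scale: bool = True,
                        seed: int = 0) -> ScreenedPCModel:
    """Fit the sPCA classifier with the screen threshold chosen by inner CV.

    For each alpha on the grid the whole screen -> PC1 -> logistic pipeline
    is refit inside each stratified training fold and scored on the held-out
    fold; the alpha with the best mean held-out AUC wins (ties to the
    smaller, more stringent alpha).  The final model is refit on all data.
    """
    y = np.asarray(outcome, dtype=int)
    gab = np.asarray(gab_weeks, dtype=float) if include_gab else None
    alpha_grid = sorted(alpha_grid)
    aucs = np.zeros((cv_repeats, len(alpha_grid)))
    subjects = np.asarray(norm.subject_ids)
    for r in range(cv_repeats):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + r)
        probs = {a: np.empty(len(y)) for a in alpha_grid}
        for train_idx, test_idx in skf.split(subjects, y):
            tr = norm.subset(subjects=subjects[train_idx])
            te_log2 = norm.log2_values.iloc[:, test_idx]
            pvals = _wilcoxon_pvalues(tr.log2_values.to_numpy(), y[train_idx].astype(bool),
                                      gab[train_idx] if include_gab else None)
            for a in alpha_grid:
                probs[a][test_idx] = _fit_predict_alpha(
                    tr, y[train_idx], gab[train_idx] if include_gab else None,
                    te_log2, gab[test_idx] if include_gab else None,
                    pvals, a, prune_frac, scale)
        for j, a in enumerate(alpha_grid):
            aucs[r, j] = roc_auc_score(y, probs[a])
    mean_auc = aucs.mean(axis=0)
    pvals = _wilcoxon_pvalues(norm.log2_values.to_numpy(), y.astype(bool),
                              gab if include_gab else None)
    # only alphas with survivors on the refit data are selectable
    selectable = np.array([(pvals < a).any() for a in alpha_grid])
    if not selectable.any():
        raise ValueError("no screening threshold yields surviving genes")
    ranked = np.where(selectable, np.round(mean_auc, 12), -np.inf)
    best = int(np.argmax(ranked))  # argmax ties to smaller alpha
    alpha = alpha_grid[best]
    mask = pvals < alpha
    genes = np.asarray(norm.gene_ids)[mask]
    order = np.argsort(pvals[mask], kind="mergesort")
    genes = list(genes[order])
    pc = pc1_fit(norm.log2_values.loc[genes], prune_frac, scale)
    coef = _fit_logistic_model(pc.scores.to_numpy(), y, gab)
    return ScreenedPCModel(alpha, genes, pc, coef, include_gab, seed,
                           pd.Series(mean_auc, index=alpha_grid))


def mann_whitney_auc(y_true: np.ndarray, score: np.ndarray) -> float:
    """AUC as the tie-corrected Mann–Whitney statistic (ties get half credit)."""
    return float(roc_auc_score(y_true, score))


def evaluate_nested(norm: NormalizedMatrix, outcome, gab_weeks=None,
                    alpha_grid=DEFAULT_ALPHA_GRID, outer_folds: int = 10,
                    cv_folds: int = 10, cv_repeats: int = 3,
                    include_gab: bool = False, prune_frac: float = 0.1,
                    scale: bool = True, seed: int = 0) -> RocResult:
    """Nested-CV evaluation: the entire selection reruns in every outer fold.

    Held-out predicted probabilities are pooled into one ROC (CV-AUC); the
    naive AUC comes from the in-sample predictions of the full-data refit.
    """
    y = np.asarray(outcome, dtype=int)
    subjects = np.asarray(norm.subject_ids)
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    heldout = np.empty(len(y))
    folds = np.empty(len(y), dtype=int)
    for k, (train_idx, test_idx) in enumerate(skf.split(subjects, y)):
        model = fit_spca_classifier(
            norm.subset(subjects=subjects[train_idx]), y[train_idx],
            np.asarray(gab_weeks, float)[train_idx] if include_gab else None,
            alpha_grid, cv_folds, cv_repeats, include_gab, prune_frac, scale,
            seed=seed + 1000 * (k + 1))
        heldout[test_idx] = model.predict_proba(
            norm.log2_values.iloc[:, test_idx],
            np.asarray(gab_weeks, float)[test_idx] if include_gab else None).to_numpy()
        folds[test_idx] = k
    cv_auc = mann_whitney_auc(y, heldout)

    full = fit_spca_classifier(norm, y, gab_weeks, alpha_grid, cv_folds,
                               cv_repeats, include_gab, prune_frac, scale, seed)
    naive = full.predict_proba(norm.log2_values,
                               gab_weeks if include_gab else None).to_numpy()
    naive_auc = mann_whitney_auc(y, naive)
    fpr, tpr, thr = roc_curve(y, heldout)
    points = pd.DataFrame({"threshold": thr, "sensitivity": tpr, "specificity": 1 - fpr})
    return RocResult(points, naive_auc, cv_auc,
                     pd.Series(folds, index=subjects), seed,
                     pd.Series(heldout, index=subjects))
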