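"""Canonical-pathway PRD classifier.

Genes are grouped into curated gene sets (GMT format; membership is
many-to-many), each pathway is reduced to the first principal component of
its member genes' expression (its eigengene), and a logistic classifier is
built over pathway scores: likelihood-ratio screening of pathways at a
threshold alpha, then forward selection of k pathways (or L1-penalized
logistic regression), with (alpha, k) chosen jointly by bivariate inner
cross-validation and honest performance estimated by an outer nested-CV
loop.  Pathway eigengenes are computed inside training folds by default so
no information leaks from held-out subjects; a global-PC mode exists for
sensitivity analysis only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from ._glm import batched_feature_lrt, batched_logistic, fit_logistic
from .matrix import NormalizedMatrix
from .spca import PCResult, RocResult, mann_whitney_auc, pc1_fit

DEFAULT_ALPHA_GRID = (0.01, 0.05, 0.10, 0.50)
DEFAULT_K_GRID = (1, 2, 3, 4, 5)
DEFAULT_LASSO_PENALTIES = (10.0, 3.0, 1.0, 0.3, 0.1)  # sklearn C, strongest last


# ----------------------------------------------------------------- gene sets

@dataclass
class GeneSetCollection:
    """Named pathway -> member gene lists (a gene may belong to several)."""

    sets: dict[str, list[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"pathway {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def bind(self, gene_ids) -> "GeneSetCollection":
        """Drop member genes absent from the expression matrix (logged) and
        pathways left empty."""
        present = set(gene_ids)
        bound, dropped = {}, 0
        for name, members in self.sets.items():
            kept = [g for g in members if g in present]
            dropped += len(members) - len(kept)
            if kept:
                bound[name] = kept
        if dropped:
            warnings.warn(f"dropped {dropped} gene-set members absent from the matrix")
        return GeneSetCollection(bound, self.source, dict(self.descriptions))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one pathway per line (name, description, members)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
        name, desc, members = fields[0], fields[1], fields[2:]
        if name in sets:
            raise ValueError(f"malformed GMT line {lineno}: duplicate pathway {name!r}")
        deduped = list(dict.fromkeys(m for m in members if m))
        if not deduped:
            raise ValueError(f"malformed GMT line {lineno}: no member genes")
        sets[name] = deduped
        descriptions[name] = desc
    if not sets:
        warnings.warn(f"empty GMT file: {path}")
    return GeneSetCollection(sets, str(path), descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "na"), *members])
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ------------------------------------------------------------ pathway scores

def pathway_scores(norm: NormalizedMatrix, sets: GeneSetCollection,
                   scale: bool = True) -> tuple[pd.DataFrame, dict[str, PCResult]]:
    """Per-pathway eigengene (PC1) scores, pathways x subjects.

    Pathways with no matrix-resident genes are dropped; genes belonging to
    no pathway play no further role.  No loading pruning is applied at the
    pathway level.
    """
    bound = sets.bind(norm.gene_ids)
    if len(bound) == 0:
        raise ValueError("no pathway has any matrix-resident gene")
    pcs: dict[str, PCResult] = {}
    rows = {}
    for name, members in bound.sets.items():
        try:
            pc = pc1_fit(norm.log2_values.loc[members], prune_frac=0.0, scale=scale)
        except ValueError:  # all member genes constant
            continue
        pcs[name] = pc
        rows[name] = pc.scores
    scores = pd.DataFrame(rows).T
    scores.columns = norm.subject_ids
    return scores, pcs


def screen_pathways(scores: pd.DataFrame, outcome, gab_weeks=None,
                    alpha: float = 0.10) -> pd.DataFrame:
    """Univariate logistic LRT per pathway score; survivors at p < alpha."""
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome does not vary")
    stat, p, penalized = batched_feature_lrt(scores.to_numpy(), y, gab_weeks)
    out = pd.DataFrame({
        "pathway": scores.index, "lrt_stat": stat, "p_value": p,
        "penalized": penalized,
    }).sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)
    out["survives"] = out["p_value"] < alpha
    return out


# --------------------------------------------------------- forward selection

def forward_select(scores: pd.DataFrame, outcome, gab_weeks=None,
                   k_max: int = 5) -> list[str]:
    """Greedy logistic forward selection over pathway scores.

    At each step the candidate maximizing the log-likelihood gain is added
    (first-come tie-break on exact ties).  Returns the selection order.
    """
    y = np.asarray(outcome, dtype=float)
    names = list(scores.index)
    X_cand = scores.to_numpy()
    n = X_cand.shape[1]
    base_cols = [np.ones(n)]
    if gab_weeks is not None:
        g = np.asarray(gab_weeks, dtype=float)
        base_cols.append((g - g.mean()) / (g.std() or 1.0))
    selected: list[str] = []
    selected_rows: list[np.ndarray] = []
    remaining = list(range(len(names)))
    for _ in range(min(k_max, len(names))):
        C = len(remaining)
        p = len(base_cols) + len(selected_rows) + 1
        X = np.empty((C, n, p))
        fixed = np.column_stack(base_cols + selected_rows)
        X[:, :, :-1] = fixed[None, :, :]
        X[:, :, -1] = X_cand[remaining]
        _, ll, _ = batched_logistic(X, y)
        best = int(np.argmax(np.round(ll, 10)))
        idx = remaining.pop(best)
        selected.append(names[idx])
        selected_rows.append(X_cand[idx])
    return selected


def _fit_logistic_on(features: np.ndarray, y: np.ndarray, gab=None
                     ) -> tuple[float, np.ndarray, float | None]:
    """ML logistic fit; returns (intercept, feature coefs, gab coef)."""
    cols = [np.ones(features.shape[1])]
    n_feat = features.shape[0]
    cols.extend(features)
    if gab is not None:
        cols.append(np.asarray(gab, dtype=float))
    X = np.column_stack(cols)
    beta, _, conv = fit_logistic(X, y)
    if not conv:
        beta, _, _ = fit_logistic(X, y, ridge=1e-3)
    gab_coef = float(beta[-1]) if gab is not None else None
    return float(beta[0]), beta[1:1 + n_feat].copy(), gab_coef


# -------------------------------------------------------------------- model

@dataclass
class PathwayModel:
    """Fitted pathway classifier (Table-2-style contents).

    ``pathway_log_or`` are the logistic coefficients of the (unit-norm,
    sign-fixed) pathway PC1 scores; ``gene_or`` are odds ratios from
    univariate logistic fits of the outcome on each standardized gene —
    descriptive annotation, not part of the predictive model.
    """

    selected_pathways: list[str]
    pcs: dict[str, PCResult]
    intercept: float
    pathway_log_or: pd.Series
    gene_or: pd.Series
    screen_threshold: float
    method: str
    seed: int
    gab_coef: float | None = None
    membership: dict[str, list[str]] = field(default_factory=dict)
    inner_cv_auc: pd.DataFrame = field(default=None, repr=False)

    def predict_proba(self, log2_values: pd.DataFrame, gab_weeks=None) -> pd.Series:
        eta = np.full(log2_values.shape[1], self.intercept)
        for name in self.selected_pathways:
            eta = eta + self.pathway_log_or[name] * self.pcs[name].project(log2_values).to_numpy()
        if self.gab_coef is not None:
            eta = eta + self.gab_coef * np.asarray(gab_weeks, dtype=float)
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=log2_values.columns)

    def to_table(self) -> pd.DataFrame:
        """Long-form pathway/gene table mirroring the printed PRD model."""
        rows = []
        for name in self.selected_pathways:
            for gene in self.membership.get(name, []):
                rows.append({
                    "pathway": name,
                    "pathway_log_or": self.pathway_log_or[name],
                    "gene": gene,
                    "gene_or": self.gene_or.get(gene, np.nan),
                })
        return pd.DataFrame(rows, columns=["pathway", "pathway_log_or", "gene", "gene_or"])


def count_model_genes(model: PathwayModel) -> int:
    """Distinct genes across the selected pathways (shared genes counted once)."""
    genes: set[str] = set()
    for name in model.selected_pathways:
        genes.update(model.membership.get(name, []))
    return len(genes)


def count_table_genes(table: pd.DataFrame, gene_column: str = "gene") -> int:
    """Distinct gene symbols in a long-form pathway-membership table."""
    return int(table[gene_column].nunique())


def load_printed_prd_model() -> pd.DataFrame:
    """The published four-pathway PRD model membership, as printed."""
    with resources.files("preemiexpr.data").joinpath(
        "prd_four_pathway_model.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _gene_odds_ratios(norm: NormalizedMatrix, genes: list[str], y: np.ndarray) -> pd.Series:
    if not genes:
        return pd.Series(dtype=float)
    X = norm.log2_values.loc[genes].to_numpy()
    scale = X.std(axis=1)
    scale[scale == 0] = 1.0
    Xs = (X - X.mean(axis=1, keepdims=True)) / scale[:, None]
    G, n = Xs.shape
    designs = np.empty((G, n, 2))
    designs[:, :, 0] = 1.0
    designs[:, :, 1] = Xs
    beta, _, conv = batched_logistic(designs, y)
    if not conv.all():
        idx = np.where(~conv)[0]
        beta_r, _, _ = batched_logistic(designs[idx], y, ridge=1e-3)
        beta[idx] = beta_r
    return pd.Series(np.exp(beta[:, 1]), index=genes)


# ------------------------------------------------------------- bivariate CV

def _project_scores(pcs: dict[str, PCResult], names, log2_values: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({name: pcs[name].project(log2_values) for name in names}).T


def _predict_eta(intercept, coefs, score_matrix: np.ndarray, gab_coef, gab):
    eta = intercept + coefs @ score_matrix
    if gab_coef is not None:
        eta = eta + gab_coef * np.asarray(gab, dtype=float)
    return eta


def fit_pathway_classifier(norm: NormalizedMatrix, sets: GeneSetCollection,
                           outcome, gab_weeks=None,
                           alpha_grid=DEFAULT_ALPHA_GRID, k_grid=DEFAULT_K_GRID,
                           method: str = "forward", cv_folds: int = 10,
                           include_gab: bool = False, pc_mode: str = "fold",
                           lasso_penalties=DEFAULT_LASSO_PENALTIES,
                           seed: int = 0) -> PathwayModel:
    """Bivariate-CV fit: (screen alpha x model size k) chosen together.

    Inner stratified CV pools held-out probabilities per grid cell; the best
    cell by AUC wins, ties preferring fewer pathways then the larger
    (more stringent downstream) alpha.  The final model is refit on all data
    at the chosen cell.  ``k`` indexes forward-selection steps, or the
    penalty grid (strong to weak) for the LASSO.
    """
    if method not in ("forward", "lasso"):
        raise ValueError("method must be 'forward' or 'lasso'")
    if method == "lasso":
        k_grid = list(range(len(lasso_penalties)))
    if not len(alpha_grid) or not len(k_grid):
        raise ValueError("grids must be non-empty")
    y = np.asarray(outcome, dtype=int)
    gab = np.asarray(gab_weeks, dtype=float) if include_gab else None
    subjects = np.asarray(norm.subject_ids)
    alpha_grid = sorted(alpha_grid)
    k_grid = sorted(k_grid)

    if pc_mode not in ("fold", "global"):
        raise ValueError("pc_mode must be 'fold' or 'global'")
    global_scores = global_pcs = None
    if pc_mode == "global":
        global_scores, global_pcs = pathway_scores(norm, sets)

    cells = [(a, k) for a in alpha_grid for k in k_grid]
    probs = {cell: np.full(len(y), 0.5) for cell in cells}
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(subjects, y):
        if pc_mode == "fold":
            tr_norm = norm.subset(subjects=subjects[train_idx])
            tr_scores, pcs = pathway_scores(tr_norm, sets)
            te_scores = _project_scores(pcs, tr_scores.index,
                                        norm.log2_values.iloc[:, test_idx])
        else:
            tr_scores = global_scores.iloc[:, train_idx]
            te_scores = global_scores.iloc[:, test_idx]
        y_tr = y[train_idx]
        gab_tr = gab[train_idx] if include_gab else None
        gab_te = gab[test_idx] if include_gab else None
        screen = screen_pathways(tr_scores, y_tr, gab_tr, alpha=1.1)
        for a in alpha_grid:
            surv = screen.loc[screen["p_value"] < a, "pathway"].tolist()
            if not surv:
                continue
            if method == "forward":
                order = forward_select(tr_scores.loc[surv], y_tr, gab_tr,
                                       k_max=max(k_grid))
                for k in k_grid:
                    chosen = order[:k]
                    feats = tr_scores.loc[chosen].to_numpy()
                    icpt, coefs, gcoef = _fit_logistic_on(feats, y_tr.astype(float), gab_tr)
                    eta = _predict_eta(icpt, coefs, te_scores.loc[chosen].to_numpy(),
                                       gcoef, gab_te)
                    probs[(a, k)][test_idx] = 1.0 / (1.0 + np.exp(-eta))
            else:
                for k in k_grid:
                    model = _lasso_fit(tr_scores.loc[surv], y_tr, gab_tr,
                                       lasso_penalties[k])
                    probs[(a, k)][test_idx] = _lasso_predict(
                        model, te_scores.loc[surv], gab_te)

    scores_all, pcs_all = (global_scores, global_pcs) if pc_mode == "global" \
        else pathway_scores(norm, sets)
    screen = screen_pathways(scores_all, y, gab, alpha=1.1)
    # only alphas with survivors on the refit data are selectable
    selectable = {a for a in alpha_grid if (screen["p_value"] < a).any()}
    if not selectable:
        raise ValueError("no screening threshold yields surviving pathways")
    auc = {cell: roc_auc_score(y, p) for cell, p in probs.items()
           if cell[0] in selectable}
    # ties: fewer pathways first, then larger (more stringent) alpha
    ranked = sorted(auc, key=lambda c: (-round(auc[c], 12), c[1], -c[0]))
    best_alpha, best_k = ranked[0]
    survivors = screen.loc[screen["p_value"] < best_alpha, "pathway"].tolist()
    if method == "forward":
        order = forward_select(scores_all.loc[survivors], y, gab, k_max=best_k)
        selected = order[:best_k]
        feats = scores_all.loc[selected].to_numpy()
        icpt, coefs, gcoef = _fit_logistic_on(feats, y.astype(float), gab)
        log_or = pd.Series(coefs, index=selected)
    else:
        model = _lasso_fit(scores_all.loc[survivors], y, gab,
                           lasso_penalties[best_k])
        coef = pd.Series(model.coef_[0][:len(survivors)], index=survivors)
        selected = list(coef.index[coef != 0])
        icpt = float(model.intercept_[0])
        gcoef = float(model.coef_[0][-1]) if include_gab else None
        log_or = coef.loc[selected]

    bound = sets.bind(norm.gene_ids)
    membership = {name: bound.sets[name] for name in selected}
    distinct_genes = sorted({g for m in membership.values() for g in m})
    gene_or = _gene_odds_ratios(norm, distinct_genes, y.astype(float))
    inner = pd.DataFrame(
        [(a, k, v) for (a, k), v in sorted(auc.items())],
        columns=["alpha", "k", "inner_cv_auc"])
    return PathwayModel(selected, {n: pcs_all[n] for n in selected}, icpt,
                        log_or, gene_or, best_alpha, method, seed, gcoef,
                        membership, inner)


def _lasso_fit(scores: pd.DataFrame, y, gab, C: float) -> LogisticRegression:
    X = scores.to_numpy().T
    if gab is not None:
        X = np.column_stack([X, np.asarray(gab, dtype=float)])
    model = LogisticRegression(penalty="l1", solver="liblinear", C=C, max_iter=500)
    model.fit(X, y)
    return model


def _lasso_predict(model: LogisticRegression, scores: pd.DataFrame, gab) -> np.ndarray:
    X = scores.to_numpy().T
    if gab is not None:
        X = np.column_stack([X, np.asarray(gab, dtype=float)])
    return model.predict_proba(X)[:, 1]


def evaluate_nested_pathways(norm: NormalizedMatrix, sets: GeneSetCollection,
                             outcome, gab_weeks=None,
                             alpha_grid=DEFAULT_ALPHA_GRID, k_grid=DEFAULT_K_GRID,
                             method: str = "forward", outer_folds: int = 10,
                             cv_folds: int = 10, include_gab: bool = False,
                             pc_mode: str = "fold", seed: int = 0) -> RocResult:
    """Nested-CV evaluation of the pathway classifier.

    The whole bivariate selection (screen threshold and model size) reruns
    inside every outer training fold; held-out probabilities are pooled into
    one ROC.  A gestational-age-only logistic baseline is evaluated on the
    same folds and attached as ``baseline``.
    """
    y = np.asarray(outcome, dtype=int)
    subjects = np.asarray(norm.subject_ids)
    gab_arr = np.asarray(gab_weeks, dtype=float) if gab_weeks is not None else None
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    heldout = np.empty(len(y))
    heldout_gab = np.empty(len(y)) if gab_arr is not None else None
    folds = np.empty(len(y), dtype=int)
    for kf, (train_idx, test_idx) in enumerate(skf.split(subjects, y)):
        model = fit_pathway_classifier(
            norm.subset(subjects=subjects[train_idx]), sets, y[train_idx],
            gab_arr[train_idx] if include_gab else None,
            alpha_grid, k_grid, method, cv_folds, include_gab, pc_mode,
            seed=seed + 1000 * (kf + 1))
        heldout[test_idx] = model.predict_proba(
            norm.log2_values.iloc[:, test_idx],
            gab_arr[test_idx] if include_gab else None).to_numpy()
        folds[test_idx] = kf
        if gab_arr is not None:
            X = np.column_stack([np.ones(len(train_idx)), gab_arr[train_idx]])
            beta, _, conv = fit_logistic(X, y[train_idx].astype(float))
            if not conv:
                beta, _, _ = fit_logistic(X, y[train_idx].astype(float), ridge=1e-3)
            heldout_gab[test_idx] = 1.0 / (1.0 + np.exp(
                -(beta[0] + beta[1] * gab_arr[test_idx])))
    cv_auc = mann_whitney_auc(y, heldout)

    full = fit_pathway_classifier(norm, sets, y,
                                  gab_arr if include_gab else None,
                                  alpha_grid, k_grid, method, cv_folds,
                                  include_gab, pc_mode, seed=seed)
    naive = full.predict_proba(norm.log2_values,
                               gab_arr if include_gab else None).to_numpy()
    naive_auc = mann_whitney_auc(y, naive)
    fpr, tpr, thr = roc_curve(y, heldout)
    points = pd.DataFrame({"threshold": thr, "sensitivity": tpr, "specificity": 1 - fpr})
    baseline = None
    if gab_arr is not None:
        bf, bt, bthr = roc_curve(y, heldout_gab)
        baseline = RocResult(
            pd.DataFrame({"threshold": bthr, "sensitivity": bt, "specificity": 1 - bf}),
            np.nan, mann_whitney_auc(y, heldout_gab),
            pd.Series(folds, index=subjects), seed,
            pd.Series(heldout_gab, index=subjects))
    return RocResult(points, naive_auc, cv_auc, pd.Series(folds, index=subjects),
                     seed, pd.Series(heldout, index=subjects), baseline)
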