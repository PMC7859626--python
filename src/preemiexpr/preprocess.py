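"""Gene/subject filtering and conditional upper-quartile normalization.

The pipeline order is fixed: (1) drop genes with a zero count in over one
third of subjects, (2) drop subjects with >75% of genes at raw count <= 5,
(3) upper-quartile normalize on the non-zero counts, (4) drop genes with
>75% of subjects at normalized (pre-log) value <= 3.  All prevalence
comparisons are strict inequalities.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import CountMatrix, NormalizedMatrix

#: stage names in the only order the pipeline runner accepts
PIPELINE_ORDER = (
    "filter_genes_zero_prevalence",
    "filter_subjects_low_reads",
    "uq_normalize",
    "filter_genes_low_normalized",
)


def filter_genes_zero_prevalence(counts: CountMatrix) -> CountMatrix:
    """Remove genes whose fraction of zero counts strictly exceeds 1/3."""
    values = counts.counts.to_numpy()
    if values.shape[0] < 1 or values.shape[1] < 3:
        raise ValueError("need at least 1 gene and 3 subjects")
    zero_frac = (values == 0).mean(axis=1)
    keep = zero_frac <= 1.0 / 3.0
    if not keep.any():
        warnings.warn("all genes removed by zero-prevalence filter")
    return CountMatrix(counts.counts.loc[keep].copy())


def filter_subjects_low_reads(
    counts: CountMatrix, raw_low: int = 5, prevalence: float = 0.75
) -> CountMatrix:
    """Remove subjects with a strict >``prevalence`` fraction of genes at raw count <= ``raw_low``."""
    if raw_low <= 0 or prevalence <= 0:
        raise ValueError("thresholds must be positive")
    low_frac = (counts.counts.to_numpy() <= raw_low).mean(axis=0)
    keep = low_frac <= prevalence
    if not keep.any():
        raise ValueError("subject filter removed every subject")
    return CountMatrix(counts.counts.loc[:, keep].copy())


def conditional_upper_quartile(column: np.ndarray) -> float:
    """75th percentile of the non-zero values (linear interpolation)."""
    nonzero = column[column > 0]
    if nonzero.size == 0:
        raise ValueError("no non-zero counts")
    return float(np.percentile(nonzero, 75))


def uq_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Conditional upper-quartile normalization, then +1 and log2.

    The per-subject factor is f_s = UQ_s / mean_s(UQ_s), where UQ_s is the
    75th percentile of the subject's non-zero counts, so factors average to
    one over the subjects present in the input.
    """
    df = counts.counts
    uq = {}
    for subject in df.columns:
        col = df[subject].to_numpy()
        if not (col > 0).any():
            raise ValueError(f"subject {subject!r} has all-zero counts")
        uq[subject] = conditional_upper_quartile(col)
    uq = pd.Series(uq, name="conditional_uq")
    factors = uq / uq.mean()
    factors.name = "norm_factor"
    normalized = df.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    log2_values = pd.DataFrame(
        np.log2(normalized + 1.0), index=df.index, columns=df.columns
    )
    return NormalizedMatrix(log2_values, factors, uq)


def filter_genes_low_normalized(
    norm: NormalizedMatrix, low: float = 3.0, prevalence: float = 0.75
) -> NormalizedMatrix:
    """Remove genes with a strict >``prevalence`` fraction of normalized (pre-log) values <= ``low``."""
    pre_log = norm.pre_log.to_numpy()
    low_frac = (pre_log <= low).mean(axis=1)
    keep = low_frac <= prevalence
    return NormalizedMatrix(
        norm.log2_values.loc[keep].copy(),
        norm.norm_factors.copy(),
        norm.conditional_uq.copy(),
        dict(norm.filter_report),
    )


def flag_outlier_subjects(norm: NormalizedMatrix, k_sd: float = 4.0) -> pd.DataFrame:
    """Report-only PCA outlier diagnostic: flag subjects beyond k SD on PC1/PC2.

    Sample exclusion for clustering/PCA outliers is never automatic because
    there is no numeric rule that defines it; this returns scores and flags
    for manual review.
    """
    x = norm.log2_values.to_numpy().T
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    scores = x @ vt[:2].T
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    flagged = (np.abs(scores) > k_sd * sd).any(axis=1)
    return pd.DataFrame(
        {"pc1": scores[:, 0], "pc2": scores[:, 1], "outlier_flag": flagged},
        index=norm.subject_ids,
    )


def run_preprocess(
    counts: CountMatrix,
    raw_low: int = 5,
    subject_prevalence: float = 0.75,
    norm_low: float = 3.0,
    gene_prevalence: float = 0.75,
    order: tuple[str, ...] = PIPELINE_ORDER,
) -> NormalizedMatrix:
    """Full preprocessing pipeline in the fixed stage order, with a filter report."""
    if tuple(order) != PIPELINE_ORDER:
        raise ValueError(f"pipeline order is fixed: {PIPELINE_ORDER}")
    n_genes0, n_subj0 = counts.shape
    step1 = filter_genes_zero_prevalence(counts)
    step2 = filter_subjects_low_reads(step1, raw_low, subject_prevalence)
    norm = uq_normalize(step2)
    out = filter_genes_low_normalized(norm, norm_low, gene_prevalence)
    out.filter_report = {
        "input_genes": n_genes0,
        "input_subjects": n_subj0,
        "genes_removed_zero_prevalence": n_genes0 - step1.shape[0],
        "subjects_removed_low_reads": n_subj0 - step2.shape[1],
        "genes_removed_low_normalized": step1.shape[0] - out.log2_values.shape[0],
        "output_genes": out.log2_values.shape[0],
        "output_subjects": out.log2_values.shape[1],
    }
    return out
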