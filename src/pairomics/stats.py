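"""Normalization, paired differential statistics and multivariate views.

All hypothesis tests run on log2(x + 1) transformed abundances. The paired
design is exploited by testing within-patient tumor-minus-control
differences (paired t-test); the rank-sum test and the AUC compare the two
condition groups directly. Multiple-testing adjustment offers
Benjamini-Hochberg (FDR) and Bonferroni (family-wise) control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .core import Condition, ExpressionMatrix, SampleDesign

logger = logging.getLogger("pairomics")

__all__ = [
    "quantile_normalize",
    "test_differential",
    "adjust_pvalues",
    "summarize_directions",
    "pca_scores",
    "hierarchical_clustering",
    "PSEUDOCOUNT",
]

#: Added to linear intensities before the log2 transform.
PSEUDOCOUNT = 1.0


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    Each sample's sorted value vector is replaced by the across-sample mean
    of sorted vectors; ties within a sample receive the mean of the
    reference quantiles they span. A single-sample matrix is returned
    unchanged (with a warning) since there is nothing to align.
    """
    arr = matrix.values()
    if arr.shape[1] < 2:
        logger.warning("quantile normalization skipped: only one sample")
        return matrix
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(len(col))
        mapped[order] = ref
        # ties share the mean of the quantile values they span
        mapped = pd.Series(mapped).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[:, j] = mapped
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        matrix.omics_kind,
    )


def _log2(values: np.ndarray, pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    return np.log2(values + pseudocount)


def test_differential(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature paired differential statistics between tumor and control.

    Returns a DataFrame with one row per feature:

    - ``mean_tumor`` / ``mean_control``: linear-scale condition means
    - ``log2_fold_change``: mean within-patient log2 difference
    - ``t_statistic``, ``p_t_raw``: paired t-test on the log2 differences
    - ``p_wmw_raw``: two-sample Wilcoxon-Mann-Whitney rank-sum test
      (tie-corrected normal approximation)
    - ``auc``: P(random tumor value > random control value), ties count 1/2
    - ``effect_size``: t divided by sqrt(number of pairs)
    - ``shapiro_p``: Shapiro-Wilk normality test of the paired differences
    - ``p_bh`` / ``p_bonferroni``: adjusted t-test p-values
    - ``direction``: sign of the log2 fold change
    - ``zero_variance``: True when all paired differences are identical;
      such features get t = NaN and p_t_raw = 1 rather than being dropped.
    """
    design.check_covers(matrix)
    n = design.n_pairs
    if n < 3:
        raise ValueError(f"need >= 3 matched pairs, got {n}")
    tumor_ids = design.samples_of(Condition.TUMOR)
    control_ids = design.samples_of(Condition.CONTROL)
    tumor = matrix.data[tumor_ids].to_numpy()
    control = matrix.data[control_ids].to_numpy()
    log_t = _log2(tumor, pseudocount)
    log_c = _log2(control, pseudocount)
    diffs = log_t - log_c

    mean_d = diffs.mean(axis=1)
    sd_d = diffs.std(axis=1, ddof=1)
    zero_var = sd_d == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean_d / (sd_d / np.sqrt(n))
    p_t = 2 * sps.t.sf(np.abs(t_stat), df=n - 1)
    t_stat[zero_var] = np.nan
    p_t[zero_var] = 1.0
    if zero_var.any():
        logger.info("%d features flagged zero-variance", int(zero_var.sum()))

    wmw = sps.mannwhitneyu(
        log_t, log_c, axis=1, alternative="two-sided", method="asymptotic"
    )
    auc = wmw.statistic / (log_t.shape[1] * log_c.shape[1])

    shapiro_p = np.full(len(diffs), np.nan)
    for i, row in enumerate(diffs):
        if not zero_var[i]:
            shapiro_p[i] = sps.shapiro(row).pvalue

    direction = np.where(mean_d > 0, "up", np.where(mean_d < 0, "down", "none"))
    result = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "mean_tumor": tumor.mean(axis=1),
            "mean_control": control.mean(axis=1),
            "log2_fold_change": mean_d,
            "t_statistic": t_stat,
            "p_t_raw": p_t,
            "p_wmw_raw": wmw.pvalue,
            "auc": auc,
            "effect_size": t_stat / np.sqrt(n),
            "shapiro_p": shapiro_p,
            "p_bh": adjust_pvalues(p_t, "bh"),
            "p_bonferroni": adjust_pvalues(p_t, "bonferroni"),
            "direction": direction,
            "zero_variance": zero_var,
        }
    )
    result = result.set_index("feature_id", drop=False)
    result.index.name = None
    return result


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m*p). ``bh``: Benjamini-Hochberg step-up with a
    running minimum from the largest rank downwards.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def summarize_directions(
    results: pd.DataFrame, alpha: float = 0.05, method: str = "bonferroni"
) -> dict:
    """Count up/down-regulated features among the significant ones.

    Fractions are percentages rounded to one decimal; with zero significant
    features they are reported as None.
    """
    col = {"bonferroni": "p_bonferroni", "bh": "p_bh"}[method.lower()]
    sig = results[results[col] < alpha]
    n_sig = len(sig)
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    frac_down = round(100 * n_down / n_sig, 1) if n_sig else None
    frac_up = round(100 * n_up / n_sig, 1) if n_sig else None
    return {
        "n_significant": n_sig,
        "n_up": n_up,
        "n_down": n_down,
        "fraction_down_pct": frac_down,
        "fraction_up_pct": frac_up,
    }


def pca_scores(
    matrix: ExpressionMatrix, pseudocount: float = PSEUDOCOUNT
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the samples on the feature-centered log2 scale.

    Returns per-sample scores (columns PC1, PC2, ...) and the fraction of
    variance each component explains (summing to 1). The sign of each
    component is fixed so its largest-magnitude feature loading is positive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    log_vals = _log2(matrix.values(), pseudocount)
    centered = log_vals - log_vals.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("matrix is constant across samples; PCA undefined")
    x = centered.T  # samples x features
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic orientation: largest |loading| of each component positive
    for k in range(len(s)):
        imax = np.argmax(np.abs(vt[k]))
        if vt[k, imax] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    keep = s > 1e-12 * s.max()
    s, u = s[keep], u[:, keep]
    scores = u * s
    var_frac = s**2 / (s**2).sum()
    score_df = pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )
    return score_df, var_frac


def hierarchical_clustering(
    matrix: ExpressionMatrix, pseudocount: float = PSEUDOCOUNT
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage agglomerative clustering of samples.

    Euclidean distance on log2 values; samples are pre-sorted by id so tied
    merge heights resolve by identifier order. Returns the scipy linkage
    matrix and the sample ids in dendrogram leaf order.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    order = sorted(matrix.sample_ids)
    log_vals = _log2(matrix.data[order].to_numpy().T, pseudocount)
    linkage = hierarchy.linkage(log_vals, method="average", metric="euclidean")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [order[i] for i in leaves]
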