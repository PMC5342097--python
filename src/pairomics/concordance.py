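"""Gene-protein concordance of differential signals.

For every mapped gene-protein pair where both layers show a nominally
significant paired t-test, the two AUC values are compared: a pair is
concordant when gene and protein sit on the same side of AUC = 0.5 (both up
or both down in tumor). The pair-level AUC vectors are additionally
summarized by their Pearson correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ProteinGeneMap

logger = logging.getLogger("pairomics")

__all__ = ["build_pairs", "concordance_stats"]


def build_pairs(
    mapping: ProteinGeneMap,
    gene_results: pd.DataFrame,
    protein_results: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene-protein pairs where both raw t-test p-values pass the threshold.

    Proteins without a gene mapping are dropped (logged); a protein mapping
    to several genes, or several proteins to one gene, expands to one row
    per pair. Columns: gene_id, protein_id, gene_auc, protein_auc,
    gene_p_raw, protein_p_raw, concordant.
    """
    unmapped = set(protein_results["feature_id"]) - set(mapping.table["protein_id"])
    if unmapped:
        logger.info("%d proteins lack a gene mapping", len(unmapped))
    pairs = mapping.table.merge(
        gene_results[["feature_id", "auc", "p_t_raw"]].rename(
            columns={"feature_id": "gene_id", "auc": "gene_auc", "p_t_raw": "gene_p_raw"}
        ),
        on="gene_id",
    ).merge(
        protein_results[["feature_id", "auc", "p_t_raw"]].rename(
            columns={
                "feature_id": "protein_id",
                "auc": "protein_auc",
                "p_t_raw": "protein_p_raw",
            }
        ),
        on="protein_id",
    )
    pairs = pairs[
        (pairs["gene_p_raw"] < p_threshold) & (pairs["protein_p_raw"] < p_threshold)
    ].reset_index(drop=True)
    pairs["concordant"] = (pairs["gene_auc"] - 0.5) * (pairs["protein_auc"] - 0.5) > 0
    return pairs[
        ["gene_id", "protein_id", "gene_auc", "protein_auc",
         "gene_p_raw", "protein_p_raw", "concordant"]
    ].sort_values(["gene_id", "protein_id"]).reset_index(drop=True)


def concordance_stats(pairs: pd.DataFrame) -> dict:
    """Pearson r of gene vs protein AUC and the percent of concordant pairs.

    Pairs with an AUC of exactly 0.5 in either layer are direction-neutral
    and excluded from the concordance denominator. The correlation needs at
    least 3 pairs and nonconstant AUC vectors; otherwise it is NaN.
    """
    n_pairs = len(pairs)
    r = np.nan
    if n_pairs >= 3:
        g, p = pairs["gene_auc"].to_numpy(), pairs["protein_auc"].to_numpy()
        if np.std(g) > 0 and np.std(p) > 0:
            r = float(sps.pearsonr(g, p).statistic)
    directional = pairs[(pairs["gene_auc"] != 0.5) & (pairs["protein_auc"] != 0.5)]
    pct = (
        100 * directional["concordant"].sum() / len(directional)
        if len(directional)
        else np.nan
    )
    return {
        "n_pairs": n_pairs,
        "n_directional": len(directional),
        "auc_correlation": r,
        "percent_concordant": float(pct) if pct == pct else np.nan,
    }
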