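"""End-to-end orchestration of the paired multi-omics analysis.

Ties the stages together in the order a study would run them: quantile
normalization per layer, paired differential statistics, the genomic
co-enrichment scan, the correlation network, the stoichiometric miRNA
influence model with degree-stratified evaluation, and gene-protein
concordance. Each stage remains usable on its own; this module only wires
defaults.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import concordance as conc
from . import corrnet, influence, proximity, stats
from .core import Condition, ExpressionMatrix, InteractionTable, OmicsKind, SampleDesign
from .synthetic import SyntheticCohort

logger = logging.getLogger("pairomics")

__all__ = [
    "normalize_layers",
    "differential_layers",
    "run_influence_analysis",
    "run_proximity_scan",
    "run_all",
]


def normalize_layers(matrices: dict[str, ExpressionMatrix]) -> dict[str, ExpressionMatrix]:
    """Quantile normalize each omics layer separately."""
    return {kind: stats.quantile_normalize(m) for kind, m in matrices.items()}


def differential_layers(
    matrices: dict[str, ExpressionMatrix], design: SampleDesign
) -> dict[str, pd.DataFrame]:
    """Paired differential statistics per layer."""
    return {kind: stats.test_differential(m, design) for kind, m in matrices.items()}


def condition_means(matrix: ExpressionMatrix, design: SampleDesign) -> dict[str, pd.Series]:
    """Linear-scale arithmetic means per condition, ordered by feature."""
    out = {}
    for cond in (Condition.CONTROL, Condition.TUMOR):
        cols = design.samples_of(cond)
        out[cond.value] = matrix.data[cols].mean(axis=1)
    return out


def run_influence_analysis(
    interactions: InteractionTable,
    mirna_norm: ExpressionMatrix,
    gene_norm: ExpressionMatrix,
    design: SampleDesign,
    gene_results: pd.DataFrame,
    support: str = "all",
    min_degrees=(1, 2, 3, 4, 5, 6),
    alpha: float = 0.05,
    adjust: str = "bonferroni",
):
    """Fit the stoichiometric model and score its direction predictions.

    Returns (weighted network, per-gene scores, accuracy table, per-gene
    evaluation detail).
    """
    filtered = influence.filter_network(
        interactions,
        support=support,
        measured_mirnas=mirna_norm.feature_ids,
        measured_genes=gene_norm.feature_ids,
    )
    gene_means = condition_means(gene_norm, design)
    mirna_means = condition_means(mirna_norm, design)
    weights = influence.compute_edge_weights(filtered, gene_means["control"])
    scores = influence.joint_influence_scores(
        weights, mirna_means["control"], mirna_means["tumor"]
    )
    table, detail = influence.evaluate_by_degree(
        scores.reset_index(drop=True),
        gene_results,
        min_degrees=min_degrees,
        alpha=alpha,
        adjust=adjust,
    )
    return weights, scores, table, detail


def run_proximity_scan(
    results_by_kind: dict[str, pd.DataFrame],
    annotation,
    chrom_lengths: dict,
    window_size: int = 1_000_000,
    step: int = 500_000,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    min_total: int = proximity.DEFAULT_MIN_TOTAL,
):
    """Linearize, scan and select co-enriched genomic regions.

    Returns (positions, window counts, enriched regions, Manhattan table).
    """
    col = {"bonferroni": "p_bonferroni", "bh": "p_bh"}[adjust.lower()]
    positions = proximity.linearize(annotation, chrom_lengths)
    significant = set()
    for res in results_by_kind.values():
        significant |= set(res.loc[res[col] < alpha, "feature_id"])
    total = sum(int(v) for v in chrom_lengths.values())
    windows = proximity.scan_windows(
        positions, significant, window_size=window_size, step=step, total_length=total
    )
    regions = proximity.select_regions(
        windows, positions, significant, chrom_lengths, min_total=min_total
    )
    manhattan = proximity.manhattan_table(results_by_kind, positions, adjust=adjust)
    return positions, windows, regions, manhattan


def run_all(
    cohort: SyntheticCohort,
    support: str = "all",
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    corr_alpha: float = 0.05,
    window_size: int = 1_000_000,
    step: int = 500_000,
) -> dict:
    """Run every stage on one cohort and collect the results in a dict."""
    raw = {
        OmicsKind.MIRNA.value: cohort.mirna,
        OmicsKind.MRNA.value: cohort.mrna,
        OmicsKind.PROTEIN.value: cohort.protein,
    }
    norm = normalize_layers(raw)
    results = differential_layers(norm, cohort.design)
    summaries = {
        kind: stats.summarize_directions(res, alpha=alpha, method=adjust)
        for kind, res in results.items()
    }
    positions, windows, regions, manhattan = run_proximity_scan(
        results, cohort.annotation, cohort.chrom_lengths,
        window_size=window_size, step=step, alpha=alpha, adjust=adjust,
    )
    n_features = sum(m.shape[0] for m in norm.values())
    threshold = corrnet.family_alpha(n_features, corr_alpha)
    edges = corrnet.pairwise_correlation_edges(list(norm.values()), threshold)
    pair_summary = corrnet.pair_type_summary(
        edges, {k: m.shape[0] for k, m in norm.items()}
    )
    weights, scores, accuracy, detail = run_influence_analysis(
        cohort.network,
        norm[OmicsKind.MIRNA.value],
        norm[OmicsKind.MRNA.value],
        cohort.design,
        results[OmicsKind.MRNA.value],
        support=support,
        alpha=alpha,
        adjust=adjust,
    )
    pairs = conc.build_pairs(
        cohort.protein_gene_map,
        results[OmicsKind.MRNA.value],
        results[OmicsKind.PROTEIN.value],
    )
    return {
        "normalized": norm,
        "differential": results,
        "direction_summaries": summaries,
        "positions": positions,
        "windows": windows,
        "regions": regions,
        "manhattan": manhattan,
        "correlation_threshold": threshold,
        "correlation_edges": edges,
        "pair_type_summary": pair_summary,
        "influence_network": weights,
        "influence_scores": scores,
        "accuracy_table": accuracy,
        "accuracy_detail": detail,
        "concordance_pairs": pairs,
        "concordance_stats": conc.concordance_stats(pairs),
    }
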