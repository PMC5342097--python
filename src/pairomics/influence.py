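"""Stoichiometric bipartite model of joint miRNA influence on target genes.

A miRNA distributes its regulatory potential over its targets in proportion
to their abundance: the edge weight from miRNA m_i to target gene g_j is

    w_ij = e(g_j) / sum_k e(g_k)

with the sum running over all l targets of m_i, so a miRNA's weights sum to
one and highly expressed competing targets dilute its influence on any
single gene. The joint influence score of gene g_j is the weighted sum of
its z targeting miRNAs' abundances,

    s(g_j) = sum_k w_kj * e(m_k).

Weights are fitted once from control-sample gene expression; evaluating s
with control versus cancer miRNA abundances gives s^N and s^C. A gene whose
joint influence rises in cancer (s^C - s^N > 0) is predicted to lose
expression (miRNAs repress their targets), and vice versa. Predictions are
scored against the measured fold-change direction of significantly
deregulated genes, stratified by the number of targeting miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import InteractionTable

logger = logging.getLogger("pairomics")

__all__ = [
    "InfluenceNetwork",
    "filter_network",
    "compute_edge_weights",
    "joint_influence_scores",
    "predict_directions",
    "evaluate_by_degree",
    "accuracy_pvalue",
]


@dataclass
class InfluenceNetwork:
    """Weighted bipartite miRNA -> gene network.

    ``edges`` has columns mirna_id, gene_id, weight; ``mirna_degree`` (l) is
    each miRNA's target count and ``gene_degree`` (z) the number of miRNAs
    targeting each gene. Per miRNA the weights sum to one.
    """

    edges: pd.DataFrame
    mirna_degree: pd.Series
    gene_degree: pd.Series

    def __post_init__(self) -> None:
        w = self.edges["weight"]
        if ((w < -1e-12) | (w > 1 + 1e-12)).any():
            raise ValueError("edge weights must lie in [0, 1]")
        sums = self.edges.groupby("mirna_id")["weight"].sum()
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)]
            raise ValueError(f"weights do not sum to 1 for miRNAs {list(bad.index)[:5]}")

    def to_graph(self, scores: pd.DataFrame | None = None,
                 gene_results: pd.DataFrame | None = None) -> nx.Graph:
        """Export as a networkx graph with weights and node annotations."""
        graph = nx.Graph()
        for mirna in self.mirna_degree.index:
            graph.add_node(mirna, kind="miRNA", n_targets=int(self.mirna_degree[mirna]))
        for gene in self.gene_degree.index:
            graph.add_node(gene, kind="gene", degree=int(self.gene_degree[gene]))
        if scores is not None:
            for row in scores.itertuples():
                if row.gene_id in graph:
                    graph.nodes[row.gene_id].update(
                        s_control=float(row.s_control),
                        s_cancer=float(row.s_cancer),
                        delta=float(row.delta),
                        predicted_direction=row.predicted_direction,
                    )
        if gene_results is not None:
            for row in gene_results.itertuples():
                if row.feature_id in graph:
                    graph.nodes[row.feature_id].update(
                        log2_fold_change=float(row.log2_fold_change)
                    )
        for row in self.edges.itertuples():
            graph.add_edge(row.mirna_id, row.gene_id,
                           weight=float(row.weight), relation="targets")
        return graph


def filter_network(
    interactions: InteractionTable,
    support: str = "all",
    measured_mirnas=None,
    measured_genes=None,
) -> InteractionTable:
    """Restrict interactions to a support level and to measured features.

    ``support='functional_strong'`` keeps only interactions validated by
    functional assays; ``'all'`` keeps everything.
    """
    if support not in ("all", "functional_strong"):
        raise ValueError(f"unknown support level {support!r}")
    t = interactions.table
    n0 = len(t)
    if support == "functional_strong":
        t = t[t["support"] == "functional_strong"]
    if measured_mirnas is not None:
        t = t[t["mirna_id"].isin(set(measured_mirnas))]
    if measured_genes is not None:
        t = t[t["gene_id"].isin(set(measured_genes))]
    dropped = n0 - len(t)
    if dropped:
        logger.info("filter_network dropped %d of %d edges", dropped, n0)
    if len(t) == 0:
        raise ValueError("no interactions left after filtering")
    return InteractionTable(t.reset_index(drop=True))


def compute_edge_weights(
    network: InteractionTable, control_gene_means: pd.Series
) -> InfluenceNetwork:
    """Derive stoichiometric edge weights from control gene expression.

    ``control_gene_means`` are linear-scale arithmetic means over control
    samples. Each miRNA's weights are its targets' means normalized to sum
    to one; a miRNA whose targets all have zero mean gets uniform weights
    1/l with a warning.
    """
    edges = network.table[["mirna_id", "gene_id"]].copy()
    missing = set(edges["gene_id"]) - set(control_gene_means.index)
    if missing:
        raise ValueError(
            f"genes in network without expression: {sorted(missing)[:10]}; "
            "filter_network first"
        )
    if (control_gene_means < 0).any():
        raise ValueError("control gene means must be nonnegative")
    edges["expr"] = edges["gene_id"].map(control_gene_means).astype(float)
    totals = edges.groupby("mirna_id")["expr"].transform("sum")
    degree = edges.groupby("mirna_id")["expr"].transform("size")
    zero_total = totals == 0
    if zero_total.any():
        n_zero = edges.loc[zero_total, "mirna_id"].nunique()
        logger.warning(
            "%d miRNAs have all-zero target expression; uniform weights used", n_zero
        )
    with np.errstate(invalid="ignore"):
        edges["weight"] = np.where(zero_total, 1.0 / degree, edges["expr"] / totals)
    edges = edges.drop(columns="expr")
    mirna_degree = edges.groupby("mirna_id").size()
    gene_degree = edges.groupby("gene_id").size()
    return InfluenceNetwork(edges, mirna_degree, gene_degree)


def joint_influence_scores(
    weights: InfluenceNetwork,
    mirna_means_control: pd.Series,
    mirna_means_cancer: pd.Series,
    genes=None,
) -> pd.DataFrame:
    """Per-gene joint influence under control and cancer miRNA abundances.

    Edge weights stay fixed at their control-derived values; only the miRNA
    abundances switch between conditions. Returns one row per gene with
    s_control, s_cancer, delta = s_cancer - s_control, degree, and the
    predicted deregulation direction. Optional ``genes`` extends the result
    to untargeted genes, which get zero scores and no_call.
    """
    edges = weights.edges
    for name, means in (("control", mirna_means_control), ("cancer", mirna_means_cancer)):
        missing = set(edges["mirna_id"]) - set(means.index)
        if missing:
            raise ValueError(
                f"miRNAs in network without {name} expression: {sorted(missing)[:10]}"
            )
    contrib_n = edges["weight"] * edges["mirna_id"].map(mirna_means_control).astype(float)
    contrib_c = edges["weight"] * edges["mirna_id"].map(mirna_means_cancer).astype(float)
    s_n = contrib_n.groupby(edges["gene_id"]).sum()
    s_c = contrib_c.groupby(edges["gene_id"]).sum()
    extra = set(genes) if genes is not None else set()
    index = pd.Index(sorted(set(s_n.index) | extra), name="gene_id")
    scores = pd.DataFrame(
        {
            "gene_id": index,
            "s_control": s_n.reindex(index, fill_value=0.0).to_numpy(),
            "s_cancer": s_c.reindex(index, fill_value=0.0).to_numpy(),
            "degree": weights.gene_degree.reindex(index, fill_value=0).astype(int).to_numpy(),
        }
    ).set_index(index)
    scores["delta"] = scores["s_cancer"] - scores["s_control"]
    return predict_directions(scores)


def predict_directions(scores: pd.DataFrame) -> pd.DataFrame:
    """Attach predictions: rising influence represses (down), falling lifts (up)."""
    scores = scores.copy()
    scores["predicted_direction"] = np.where(
        scores["delta"] > 0, "down", np.where(scores["delta"] < 0, "up", "no_call")
    )
    return scores


def evaluate_by_degree(
    predictions: pd.DataFrame,
    gene_results: pd.DataFrame,
    min_degrees=(1, 2, 3, 4, 5, 6),
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degree-stratified prediction accuracy on significant genes.

    Evaluated genes are those significant at adjusted p < ``alpha`` whose
    measured direction (sign of log2 fold change) is defined and whose
    prediction is not no_call. For each minimum degree d the accuracy over
    genes targeted by >= d miRNAs is reported with a one-sided exact
    binomial p-value against chance (0.5). Returns (accuracy table,
    per-gene detail with correctness flags).
    """
    col = {"bonferroni": "p_bonferroni", "bh": "p_bh", "raw": "p_t_raw"}[adjust.lower()]
    sig = gene_results[
        (gene_results[col] < alpha) & (gene_results["direction"].isin(["up", "down"]))
    ]
    detail = predictions.reset_index(drop=True).merge(
        sig[["feature_id", "direction", "log2_fold_change"]],
        left_on="gene_id",
        right_on="feature_id",
        how="inner",
    )
    detail = detail[detail["predicted_direction"] != "no_call"]
    detail = detail.rename(columns={"direction": "measured_direction"})
    detail["correct"] = detail["predicted_direction"] == detail["measured_direction"]
    detail = detail[
        ["gene_id", "degree", "predicted_direction", "measured_direction",
         "log2_fold_change", "correct"]
    ].sort_values("gene_id").reset_index(drop=True)

    records = []
    for d in min_degrees:
        stratum = detail[detail["degree"] >= d]
        n_eval = len(stratum)
        n_correct = int(stratum["correct"].sum())
        records.append(
            {
                "min_degree": d,
                "n_evaluated": n_eval,
                "n_correct": n_correct,
                "accuracy_pct": round(100 * n_correct / n_eval, 1) if n_eval else np.nan,
                "p_binomial": accuracy_pvalue(n_correct, n_eval),
            }
        )
    return pd.DataFrame(records), detail


def accuracy_pvalue(n_correct: int, n_evaluated: int, null_prob: float = 0.5) -> float:
    """One-sided exact binomial tail P(X >= n_correct), X ~ Bin(n, null_prob)."""
    if not 0 <= n_correct <= n_evaluated:
        raise ValueError("need 0 <= n_correct <= n_evaluated")
    if n_evaluated == 0:
        return float("nan")
    return float(sps.binom.sf(n_correct - 1, n_evaluated, null_prob))
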