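"""Stoichiometric influence model: weights, scores, predictions, accuracy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairomics import (
    InteractionTable,
    SimulationConfig,
    accuracy_pvalue,
    compute_edge_weights,
    evaluate_by_degree,
    filter_network,
    generate_cohort,
    joint_influence_scores,
    predict_directions,
)


def _interactions(rows):
    return InteractionTable(
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "support"])
    )


TOY = _interactions(
    [("mirA", "g1", "other"), ("mirA", "g2", "other"), ("mirB", "g1", "functional_strong")]
)


class TestFilterNetwork:
    def test_functional_subset(self):
        out = filter_network(TOY, support="functional_strong")
        assert len(out) == 1
        assert out.table.iloc[0]["mirna_id"] == "mirB"

    def test_unmeasured_gene_dropped(self):
        out = filter_network(TOY, measured_genes={"g1"})
        assert set(out.table["gene_id"]) == {"g1"}

    def test_all_is_superset_of_functional(self):
        all_edges = set(map(tuple, filter_network(TOY, "all").table[["mirna_id", "gene_id"]].values))
        func = set(map(tuple, filter_network(TOY, "functional_strong").table[["mirna_id", "gene_id"]].values))
        assert func <= all_edges

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError, match="no interactions"):
            filter_network(TOY, measured_genes={"absent"})


class TestEdgeWeights:
    def test_single_target_weight_one(self):
        net = _interactions([("mirB", "g1", "other")])
        weights = compute_edge_weights(net, pd.Series({"g1": 123.0}))
        assert weights.edges["weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_proportional_to_target_expression(self):
        weights = compute_edge_weights(TOY, pd.Series({"g1": 30.0, "g2": 10.0}))
        w = weights.edges.set_index(["mirna_id", "gene_id"])["weight"]
        assert w[("mirA", "g1")] == pytest.approx(0.75)
        assert w[("mirA", "g2")] == pytest.approx(0.25)
        assert w[("mirB", "g1")] == pytest.approx(1.0)

    def test_all_zero_targets_get_uniform_weights(self, caplog):
        with caplog.at_level("WARNING", logger="pairomics"):
            weights = compute_edge_weights(TOY, pd.Series({"g1": 0.0, "g2": 0.0}))
        w = weights.edges.set_index(["mirna_id", "gene_id"])["weight"]
        assert w[("mirA", "g1")] == pytest.approx(0.5)
        assert any("uniform" in rec.message for rec in caplog.records)

    def test_missing_gene_expression_rejected(self):
        with pytest.raises(ValueError, match="filter_network"):
            compute_edge_weights(TOY, pd.Series({"g1": 1.0}))

    def test_scale_invariance_of_weights(self):
        means = pd.Series({"g1": 30.0, "g2": 10.0})
        w1 = compute_edge_weights(TOY, means).edges["weight"]
        w2 = compute_edge_weights(TOY, means * 7.3).edges["weight"]
        assert np.allclose(w1, w2)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_weight_conservation_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n_mir, n_gene = rng.integers(2, 8), rng.integers(2, 30)
        genes = [f"g{i}" for i in range(n_gene)]
        rows = []
        for i in range(n_mir):
            for g in rng.choice(genes, size=rng.integers(1, n_gene + 1), replace=False):
                rows.append((f"m{i}", g, "other"))
        net = _interactions(rows)
        means = pd.Series(rng.random(n_gene) * 100, index=genes)
        weights = compute_edge_weights(net, means)
        sums = weights.edges.groupby("mirna_id")["weight"].sum()
        assert np.allclose(sums, 1.0)


class TestJointInfluence:
    def test_hand_worked_two_mirna_example(self):
        weights = compute_edge_weights(TOY, pd.Series({"g1": 30.0, "g2": 10.0}))
        scores = joint_influence_scores(
            weights,
            pd.Series({"mirA": 4.0, "mirB": 1.0}),
            pd.Series({"mirA": 2.0, "mirB": 5.0}),
        )
        g1, g2 = scores.loc["g1"], scores.loc["g2"]
        assert g1["s_control"] == pytest.approx(4.0)
        assert g1["s_cancer"] == pytest.approx(6.5)
        assert g1["delta"] == pytest.approx(2.5)
        assert g1["predicted_direction"] == "down"
        assert g2["s_control"] == pytest.approx(1.0)
        assert g2["s_cancer"] == pytest.approx(0.5)
        assert g2["delta"] == pytest.approx(-0.5)
        assert g2["predicted_direction"] == "up"

    def test_untargeted_gene_scores_zero(self):
        weights = compute_edge_weights(TOY, pd.Series({"g1": 30.0, "g2": 10.0}))
        scores = joint_influence_scores(
            weights,
            pd.Series({"mirA": 4.0, "mirB": 1.0}),
            pd.Series({"mirA": 2.0, "mirB": 5.0}),
            genes=["g3"],
        )
        g3 = scores.loc["g3"]
        assert g3["s_control"] == 0 and g3["delta"] == 0
        assert g3["predicted_direction"] == "no_call"

    def test_missing_mirna_expression_rejected(self):
        weights = compute_edge_weights(TOY, pd.Series({"g1": 30.0, "g2": 10.0}))
        with pytest.raises(ValueError, match="mirB"):
            joint_influence_scores(
                weights, pd.Series({"mirA": 4.0}), pd.Series({"mirA": 2.0})
            )

    def test_delta_scales_with_mirna_abundance(self):
        # doubling all miRNA means doubles delta but flips no prediction
        weights = compute_edge_weights(TOY, pd.Series({"g1": 30.0, "g2": 10.0}))
        base_n = pd.Series({"mirA": 4.0, "mirB": 1.0})
        base_c = pd.Series({"mirA": 2.0, "mirB": 5.0})
        s1 = joint_influence_scores(weights, base_n, base_c)
        s2 = joint_influence_scores(weights, base_n * 2, base_c * 2)
        assert np.allclose(s2["delta"], 2 * s1["delta"])
        assert (s1["predicted_direction"] == s2["predicted_direction"]).all()

    def test_single_target_gene_prediction_opposes_mirna_change(self):
        # a gene targeted by exactly one miRNA inherits the opposite direction
        net = _interactions([("mirX", "gA", "other")])
        weights = compute_edge_weights(net, pd.Series({"gA": 50.0}))
        up = joint_influence_scores(
            weights, pd.Series({"mirX": 1.0}), pd.Series({"mirX": 3.0})
        )
        down = joint_influence_scores(
            weights, pd.Series({"mirX": 3.0}), pd.Series({"mirX": 1.0})
        )
        assert up.loc["gA", "predicted_direction"] == "down"
        assert down.loc["gA", "predicted_direction"] == "up"

    def test_vectorized_scores_match_per_edge_loop(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(200)]
        rows = []
        for i in range(80):
            for g in rng.choice(genes, size=rng.integers(1, 10), replace=False):
                rows.append((f"m{i}", g, "other"))
        net = _interactions(rows)
        gene_means = pd.Series(rng.random(200) * 100, index=genes)
        mir_ids = sorted({r[0] for r in rows})
        mn = pd.Series(rng.random(len(mir_ids)) * 50, index=mir_ids)
        mc = pd.Series(rng.random(len(mir_ids)) * 50, index=mir_ids)
        weights = compute_edge_weights(net, gene_means)
        scores = joint_influence_scores(weights, mn, mc)
        # per-edge loop oracle
        s_n, s_c = {}, {}
        for row in weights.edges.itertuples():
            s_n[row.gene_id] = s_n.get(row.gene_id, 0) + row.weight * mn[row.mirna_id]
            s_c[row.gene_id] = s_c.get(row.gene_id, 0) + row.weight * mc[row.mirna_id]
        for g in s_n:
            assert scores.loc[g, "s_control"] == pytest.approx(s_n[g])
            assert scores.loc[g, "s_cancer"] == pytest.approx(s_c[g])


class TestPredictDirections:
    @pytest.mark.parametrize(
        "delta,expected", [(2.5, "down"), (-0.5, "up"), (0.0, "no_call")]
    )
    def test_direction_rule(self, delta, expected):
        scores = pd.DataFrame({"delta": [delta]})
        assert predict_directions(scores)["predicted_direction"].iloc[0] == expected


def _prediction_frame(rows):
    """rows: (gene_id, degree, predicted, measured)."""
    preds = pd.DataFrame(
        [(g, d, p) for g, d, p, _ in rows],
        columns=["gene_id", "degree", "predicted_direction"],
    )
    results = pd.DataFrame(
        {
            "feature_id": [g for g, *_ in rows],
            "direction": [m for *_, m in rows],
            "log2_fold_change": [1.0 if m == "up" else -1.0 for *_, m in rows],
            "p_bonferroni": 0.001,
            "p_bh": 0.001,
            "p_t_raw": 0.001,
        }
    )
    return preds, results


class TestEvaluateByDegree:
    def test_high_degree_validated_network_accuracy(self):
        # 13 significant genes targeted by >= 6 miRNAs: 12 correct calls and
        # one up-regulated gene mispredicted as down
        down = ["CD44", "ZEB1", "ZEB2", "BMPR2", "RECK", "TGFBR2", "PURA", "KAT2B"]
        up = ["DNMT1", "CCNE2", "CDK4", "EZH2"]
        rows = [(g, 6 + i % 3, "down", "down") for i, g in enumerate(down)]
        rows += [(g, 6 + i % 3, "up", "up") for i, g in enumerate(up)]
        rows += [("HIF1A", 7, "down", "up")]
        preds, results = _prediction_frame(rows)
        table, detail = evaluate_by_degree(preds, results, min_degrees=(1, 6))
        stratum = table.set_index("min_degree").loc[6]
        assert stratum["n_evaluated"] == 13
        assert stratum["n_correct"] == 12
        assert stratum["accuracy_pct"] == 92.3
        assert stratum["p_binomial"] == pytest.approx(14 / 8192)
        wrong = detail[~detail["correct"]]
        assert list(wrong["gene_id"]) == ["HIF1A"]

    def test_all_correct_gives_hundred(self):
        preds, results = _prediction_frame([("a", 1, "up", "up"), ("b", 2, "down", "down")])
        table, _ = evaluate_by_degree(preds, results, min_degrees=(1,))
        assert table["accuracy_pct"].iloc[0] == 100.0

    def test_degree_above_max_gives_na(self):
        preds, results = _prediction_frame([("a", 2, "up", "up")])
        table, _ = evaluate_by_degree(preds, results, min_degrees=(5,))
        assert np.isnan(table["accuracy_pct"].iloc[0])

    def test_nonsignificant_genes_excluded(self):
        preds, results = _prediction_frame([("a", 1, "up", "up"), ("b", 1, "down", "up")])
        results.loc[results["feature_id"] == "b", "p_bonferroni"] = 0.5
        table, detail = evaluate_by_degree(preds, results, min_degrees=(1,))
        assert table["n_evaluated"].iloc[0] == 1
        assert list(detail["gene_id"]) == ["a"]

    def test_strong_coupling_cohort_recovers_directions(self):
        cfg = SimulationConfig(
            seed=3, n_mirna=60, n_gene=400, n_protein=30,
            coupling_strength=5.0, feature_noise_sd=0.1,
            fraction_deregulated_gene=0.0,
        )
        cohort = generate_cohort(cfg)
        from pairomics import pipeline
        from pairomics.stats import test_differential

        # synthetic abundances carry no technical bias, so the model is
        # evaluated on the raw matrices
        gene_res = test_differential(cohort.mrna, cohort.design)
        _, _, table, _ = pipeline.run_influence_analysis(
            cohort.network, cohort.mirna, cohort.mrna, cohort.design, gene_res,
            min_degrees=(1,),
        )
        assert table["n_evaluated"].iloc[0] >= 20
        assert table["accuracy_pct"].iloc[0] > 90


class TestAccuracyPvalue:
    def test_exact_binomial_tails(self):
        assert accuracy_pvalue(12, 13) == pytest.approx(14 / 8192)
        assert accuracy_pvalue(5, 10) == pytest.approx(638 / 1024)

    def test_empty_evaluation_is_na(self):
        assert np.isnan(accuracy_pvalue(0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            accuracy_pvalue(5, 3)
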