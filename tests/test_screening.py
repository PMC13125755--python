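"""Essentiality prediction, adaptation check, screen labeling and MCC."""

import numpy as np
import pandas as pd
import pytest

from regmis import (BooleanNetwork, ConfusionCounts, DependencyScores,
                    ExpressionMatrix, GMIS, InterventionSet, Lit, Not,
                    ScreeningConfig, adaptation_check, compute_mcc,
                    evaluate_predictions, label_dependencies,
                    make_screen_fixture, make_toy_gem, predict_essential,
                    random_boolean_network)


def gmis_of(KO=(), KI=()):
    return GMIS(interventions=InterventionSet(KO=KO, KI=KI), blocked=frozenset())


def expr_matrix(data: dict[str, dict[str, float]]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(data))


class TestPredictEssential:
    def test_unique_highly_expressed_knockout_is_called(self):
        gm = gmis_of(KO=["g1", "g2"])
        expr = expr_matrix({"s1": {"g1": 0.0, "g2": 5.0}})
        pred = predict_essential([gm], expr)
        assert set(pred["s1"]) == {"g2"}

    def test_two_expressed_knockouts_give_no_call(self):
        gm = gmis_of(KO=["g1", "g2"])
        expr = expr_matrix({"s1": {"g1": 5.0, "g2": 5.0}})
        assert predict_essential([gm], expr)["s1"] == {}

    def test_knockin_context_must_be_expressed(self):
        gm = gmis_of(KO=["g3"], KI=["g4"])
        on = expr_matrix({"s1": {"g3": 5.0, "g4": 5.0}})
        off = expr_matrix({"s1": {"g3": 5.0, "g4": 0.0}})
        assert set(predict_essential([gm], on)["s1"]) == {"g3"}
        assert predict_essential([gm], off)["s1"] == {}

    def test_provenance_points_at_supporting_gmis(self):
        gms = [gmis_of(KO=["g1", "g2"]), gmis_of(KO=["g2"])]
        expr = expr_matrix({"s1": {"g1": 0.0, "g2": 5.0}})
        pred = predict_essential(gms, expr)
        assert pred["s1"]["g2"] == [0, 1]

    def test_missing_gene_listed_in_error(self):
        gm = gmis_of(KO=["g1", "gX"])
        expr = expr_matrix({"s1": {"g1": 0.0}})
        with pytest.raises(KeyError, match="gX"):
            predict_essential([gm], expr)

    def test_calls_survive_threshold_raise_when_own_context_stays_high(self):
        """If a call exists at threshold t and the called gene plus all
        knock-in genes still exceed a higher threshold t', the call survives
        at t' (the 'others not expressed' clause only relaxes)."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(6)]
        gms = [gmis_of(KO=genes[:3]), gmis_of(KO=genes[3:5], KI=[genes[5]])]
        for _ in range(20):
            df = pd.DataFrame(rng.uniform(0, 4, size=(6, 3)), index=genes,
                              columns=["s1", "s2", "s3"])
            t, t2 = 1.0, 2.0
            low = predict_essential(gms, ExpressionMatrix(df), ScreeningConfig(t))
            high = predict_essential(gms, ExpressionMatrix(df), ScreeningConfig(t2))
            for s, calls in low.items():
                for g, idxs in calls.items():
                    for k in idxs:
                        ki = gms[k].interventions.KI
                        if df.at[g, s] > t2 and all(df.at[x, s] > t2 for x in ki):
                            assert g in high[s]


class TestAdaptationCheck:
    def test_singleton_gmis_vacuously_passes(self):
        bn = BooleanNetwork({"g1": Lit("g1")})
        assert adaptation_check(bn, gmis_of(KO=["g1"]))

    def test_repression_rescue_fails(self):
        bn = BooleanNetwork({"g1": Lit("g1"), "g2": Not(Lit("g1"))})
        assert not adaptation_check(bn, gmis_of(KO=["g1", "g2"]))

    def test_coactivation_passes(self):
        bn = BooleanNetwork({"g1": Lit("g1"), "g2": Lit("g1")})
        assert adaptation_check(bn, gmis_of(KO=["g1", "g2"]))

    def test_unlinked_members_always_pass(self):
        for seed in range(1, 6):
            bn = random_boolean_network(1, 1, seed)
            f = {x: bn.f[x] for x in bn.nodes}
            for g in ("a", "b", "c"):
                f[g] = Lit(g)
            free_net = BooleanNetwork(f)
            assert adaptation_check(free_net, gmis_of(KO=["a", "b"], KI=["c"]))


class TestLabelsAndMCC:
    def test_depmap_threshold_boundary_inclusive(self):
        scores = DependencyScores(pd.DataFrame({"s1": [-0.61, -0.6, -0.59]},
                                               index=["a", "b", "c"]), "depmap")
        labels = label_dependencies(scores)
        assert labels["s1"].tolist() == [1.0, 1.0, 0.0]

    def test_project_score_boundary_exclusive(self):
        scores = DependencyScores(pd.DataFrame({"s1": [0.5, 0.0, -0.1]},
                                               index=["a", "b", "c"]), "project_score")
        labels = label_dependencies(scores)
        assert labels["s1"].tolist() == [1.0, 0.0, 0.0]

    def test_missing_scores_stay_missing(self):
        scores = DependencyScores(pd.DataFrame({"s1": [np.nan, -1.0]},
                                               index=["a", "b"]), "depmap")
        labels = label_dependencies(scores)
        assert pd.isna(labels.at["a", "s1"]) and labels.at["b", "s1"] == 1.0

    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(TP=10, TN=10, FP=0, FN=0), 1.0),
        (ConfusionCounts(TP=0, TN=0, FP=10, FN=10), -1.0),
        (ConfusionCounts(TP=1, FP=1, TN=1, FN=1), 0.0),
        (ConfusionCounts(TP=0, FP=0, TN=5, FN=0), 0.0),  # zero-factor convention
    ])
    def test_mcc_values(self, counts, expected):
        assert compute_mcc(counts) == pytest.approx(expected)

    def test_mcc_matches_sklearn(self):
        from sklearn.metrics import matthews_corrcoef
        rng = np.random.default_rng(5)
        for _ in range(20):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            c = ConfusionCounts(
                TP=int(((y_true == 1) & (y_pred == 1)).sum()),
                FP=int(((y_true == 0) & (y_pred == 1)).sum()),
                TN=int(((y_true == 0) & (y_pred == 0)).sum()),
                FN=int(((y_true == 1) & (y_pred == 0)).sum()))
            assert compute_mcc(c) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestEvaluatePredictions:
    def test_perfect_agreement(self):
        labels = pd.DataFrame({"s1": [1.0, 0.0, 0.0, 1.0, 0.0]},
                              index=list("abcde"))
        pred = {"s1": {"a", "d"}}
        res = evaluate_predictions(pred, labels, set("abcde"))
        assert res.pooled_mcc == 1.0

    def test_all_negative_labels_zero_by_convention(self):
        labels = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        res = evaluate_predictions({}, labels, {"a", "b"})
        assert res.per_sample["s1"].TN == 2
        assert res.per_sample_mcc["s1"] == 0.0

    def test_pooled_counts_are_sums(self):
        labels = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 0.0]},
                              index=["a", "b"])
        pred = {"s1": {"a"}, "s2": {"b"}}  # one FP in sample 2
        res = evaluate_predictions(pred, labels, {"a", "b"})
        total = res.per_sample["s1"] + res.per_sample["s2"]
        assert (res.pooled.TP, res.pooled.FP, res.pooled.TN, res.pooled.FN) == \
            (total.TP, total.FP, total.TN, total.FN) == (1, 1, 2, 0)

    def test_empty_universe_rejected(self):
        labels = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            evaluate_predictions({}, labels, set())


class TestEndToEndRecovery:
    def _pipeline_mcc(self, noise, seed=3):
        b = make_toy_gem("repressor")
        sb = make_screen_fixture(b, n_samples=10, noise=noise, seed=seed)
        gms = [gmis_of(KO=e["KO"], KI=e["KI"]) for e in sb.ground_truth["gmis"]]
        pred = predict_essential(gms, sb.expression)
        labels = label_dependencies(sb.scores)
        universe = {g for gm in gms for g in gm.interventions.KO}
        return evaluate_predictions(pred, labels, universe).pooled_mcc

    def test_noise_free_screen_recovered_exactly(self):
        assert self._pipeline_mcc(noise=0.0) == 1.0

    def test_label_noise_degrades_mcc(self):
        assert self._pipeline_mcc(noise=0.1) < 1.0

    def test_fully_flipped_labels_invert_score(self):
        assert self._pipeline_mcc(noise=1.0) <= 0.0
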