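"""Grouped CV mechanics, metrics, sweeps, importance and ablations.

Model-refitting tests run on the small synthetic configuration so the
default suite stays fast; the full-size study conditions are exercised by
the acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

import kinoviab as kv
from kinoviab.modeling import DoseOnlyBaseline, planted_importance_rank_test


class TestGroupFolds:
    def test_balanced_folds(self):
        combos = [(f"L{i}", "c") for i in range(20)]
        folds = kv.make_group_folds(combos, n_folds=10, seed=0)
        sizes = pd.Series(list(folds.mapping.values())).value_counts()
        assert (sizes == 2).all()

    def test_deterministic(self):
        combos = [(f"L{i}", f"c{j}") for i in range(5) for j in range(4)]
        a = kv.make_group_folds(combos, n_folds=4, seed=3)
        b = kv.make_group_folds(combos, n_folds=4, seed=3)
        assert a.mapping == b.mapping

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            kv.make_group_folds([("L", "c")], n_folds=2, seed=0)

    def test_every_combo_in_exactly_one_fold(self, small_table, small_folds):
        fold_of = small_folds.fold_of(small_table)
        per_combo = pd.DataFrame({
            "combo": list(zip(small_table["cell_line"],
                              small_table["compound"])),
            "fold": fold_of}).groupby("combo")["fold"].nunique()
        assert (per_combo == 1).all()


class TestBaseline:
    def test_groupwise_mean(self):
        model = DoseOnlyBaseline().fit([1e-6, 1e-6, 1e-7], [0.4, 0.6, 1.0])
        assert model.predict([1e-6])[0] == pytest.approx(0.5)
        assert model.predict([1e-7])[0] == pytest.approx(1.0)

    def test_unseen_concentration_rejected(self):
        model = DoseOnlyBaseline().fit([1e-6], [0.5])
        with pytest.raises(ValueError):
            model.predict([1e-8])

    def test_matches_brute_force_group_means(self, small_table, small_folds):
        res = kv.cross_validate(small_table,
                                kv.ModelSpec(family="baseline_dose"),
                                small_folds)
        fold_of = small_folds.fold_of(small_table)
        for fold in range(1, small_folds.n_folds + 1):
            train = small_table.loc[fold_of != fold]
            test_idx = np.nonzero(fold_of == fold)[0]
            means = train.groupby("concentration")["viability"].mean()
            for i in test_idx:
                x = small_table.loc[i, "concentration"]
                assert res.predictions.loc[i, "predicted"] == \
                    pytest.approx(means[x])


class TestEvaluate:
    def test_perfect_fit(self):
        assert kv.evaluate([1, 2, 3], [1, 2, 3]) == (1.0, 0.0)

    def test_constant_shift_under_pearson(self):
        y = np.array([0.1, 0.5, 0.9, 0.3])
        r2, rmse = kv.evaluate(y + 0.1, y)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.1)

    def test_matches_brute_force_formulas(self):
        rng = np.random.default_rng(2)
        p, o = rng.normal(size=50), rng.normal(size=50)
        r2, rmse = kv.evaluate(p, o)
        r = np.sum((p - p.mean()) * (o - o.mean())) / np.sqrt(
            np.sum((p - p.mean()) ** 2) * np.sum((o - o.mean()) ** 2))
        assert r2 == pytest.approx(r ** 2, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(np.mean((p - o) ** 2)),
                                     abs=1e-12)
        r2c, _ = kv.evaluate(p, o, r2_mode="cod")
        assert r2c == pytest.approx(
            1 - np.sum((p - o) ** 2) / np.sum((o - o.mean()) ** 2),
            abs=1e-12)

    def test_zero_variance_predictions_flagged(self):
        with pytest.warns(UserWarning):
            r2, rmse = kv.evaluate([0.5, 0.5, 0.5], [0.1, 0.5, 0.9])
        assert r2 == 0.0


class TestCrossValidate:
    def test_baseline_r2_independent_of_k(self, small_table, small_folds):
        a = kv.cross_validate(small_table,
                              kv.ModelSpec(family="baseline_dose",
                                           n_features=1), small_folds)
        b = kv.cross_validate(small_table,
                              kv.ModelSpec(family="baseline_dose",
                                           n_features=10), small_folds)
        assert a.r2 == b.r2 and a.rmse == b.rmse

    def test_perfectly_recoverable_signal(self, small_table, small_folds):
        """If the response equals one inhibition feature, a linear model
        with in-fold screening recovers it almost exactly."""
        table = small_table.copy()
        act_cols = [c for c in table.columns if c.startswith("act_")]
        signal = next(c for c in act_cols if table[c].std() > 0.05)
        table["viability"] = table[signal]
        res = kv.cross_validate(table, kv.ModelSpec(family="linear",
                                                    n_features=1),
                                small_folds)
        assert res.r2 >= 0.999

    def test_no_leakage_predictions_pure_function_of_training(
            self, small_table, small_folds):
        spec = kv.ModelSpec(family="random_forest", n_features=20, trees=30,
                            seed=0)
        a = kv.cross_validate(small_table, spec, small_folds)
        shuffled = small_table.copy()
        fold_of = small_folds.fold_of(shuffled)
        # perturb held-out responses of fold 1; fold-1 predictions must not move
        mask = fold_of == 1
        shuffled.loc[mask, "viability"] = \
            shuffled.loc[mask, "viability"].sample(frac=1.0,
                                                   random_state=1).values
        b = kv.cross_validate(shuffled, spec, small_folds)
        np.testing.assert_allclose(a.predictions.loc[mask, "predicted"],
                                   b.predictions.loc[mask, "predicted"])

    def test_family_ordering_rf_linear_baseline(self, small_table,
                                                small_folds):
        """Out-of-fold R^2: random forest >= linear >= dose-only baseline
        (the expected qualitative ordering)."""
        k = 20
        rf = kv.cross_validate(small_table,
                               kv.ModelSpec(family="random_forest",
                                            n_features=k, trees=60, seed=0),
                               small_folds)
        lin = kv.cross_validate(small_table,
                                kv.ModelSpec(family="linear", n_features=k),
                                small_folds)
        base = kv.cross_validate(small_table,
                                 kv.ModelSpec(family="baseline_dose"),
                                 small_folds)
        assert rf.r2 >= lin.r2 >= base.r2

    def test_gradient_boosting_runs(self, small_table, small_folds):
        res = kv.cross_validate(small_table,
                                kv.ModelSpec(family="gradient_boosting",
                                             n_features=20, seed=0),
                                small_folds)
        assert res.r2 > 0.0
        assert len(res.predictions) == len(small_table)

    def test_fold_selections_recorded(self, small_table, small_folds):
        res = kv.cross_validate(small_table,
                                kv.ModelSpec(family="random_forest",
                                             n_features=15, trees=30,
                                             seed=0), small_folds)
        assert len(res.fold_selections) == small_folds.n_folds
        assert all(len(s) == 15 for s in res.fold_selections)
        frac, incl = kv.selection_stability(res.fold_selections)
        assert 0.0 <= frac <= 1.0


class TestSubsetMetrics:
    def test_single_group_equals_global(self, small_table, small_folds):
        res = kv.cross_validate(small_table,
                                kv.ModelSpec(family="baseline_dose"),
                                small_folds)
        res.predictions["compound"] = "one"
        sub = kv.subset_metrics(res, by="compound")
        assert len(sub) == 1
        assert sub["r2"].iloc[0] == pytest.approx(res.r2)
        assert sub["rmse"].iloc[0] == pytest.approx(res.rmse)

    def test_perfect_predictions_propagate(self):
        preds = pd.DataFrame({
            "cell_line": ["L1"] * 4 + ["L2"] * 4,
            "compound": ["c"] * 8,
            "concentration": list(range(8)),
            "observed": np.linspace(0.1, 0.9, 8),
            "predicted": np.linspace(0.1, 0.9, 8),
            "fold": 1})
        res = kv.ModelResult(preds, 1.0, 0.0, [], kv.ModelSpec())
        sub = kv.subset_metrics(res, by="cell_line")
        assert np.allclose(sub["r2"], 1.0)
        assert np.allclose(sub["rmse"], 0.0)

    def test_matches_looped_evaluate(self, small_table, small_folds):
        res = kv.cross_validate(small_table,
                                kv.ModelSpec(family="linear", n_features=10),
                                small_folds)
        sub = kv.subset_metrics(res, by="compound").set_index("compound")
        for cmpd, grp in res.predictions.groupby("compound"):
            if len(grp) < 3:
                continue
            r2, rmse = kv.evaluate(grp["predicted"], grp["observed"])
            assert sub.loc[cmpd, "r2"] == pytest.approx(r2)
            assert sub.loc[cmpd, "rmse"] == pytest.approx(rmse)


class TestSweep:
    def test_singleton_grid_equals_cross_validate(self, small_table,
                                                  small_folds):
        base = kv.ModelSpec(family="random_forest", n_features=15, trees=40,
                            predictors_per_split=5, min_node_size=5, seed=0)
        sweep = kv.hyperparameter_sweep(
            small_table, small_folds,
            grid={"trees": [40], "predictors_per_split": [5],
                  "min_node_size": [5]}, base_spec=base)
        direct = kv.cross_validate(small_table, base, small_folds)
        assert len(sweep) == 1
        assert sweep["r2"].iloc[0] == pytest.approx(direct.r2)

    def test_duplicated_point_deterministic(self, small_table, small_folds):
        base = kv.ModelSpec(family="random_forest", n_features=15, seed=0)
        grid = {"trees": [30], "predictors_per_split": [5],
                "min_node_size": [5, 5]}
        sweep = kv.hyperparameter_sweep(small_table, small_folds, grid=grid,
                                        base_spec=base)
        assert sweep["r2"].iloc[0] == sweep["r2"].iloc[1]


class TestImportance:
    def test_pure_noise_importance_unremarkable(self, small_table):
        """No feature should stand out when the response is noise."""
        rng = np.random.default_rng(0)
        table = small_table.copy()
        table["viability"] = rng.normal(size=len(table))
        final = kv.fit_final_model(table, k=20,
                                   spec=kv.ModelSpec(family="random_forest",
                                                     n_features=20, trees=50,
                                                     seed=0))
        names = final.selected_features + ["log10_dose"]
        imp = kv.importance(final.model, names)
        z = (imp["importance"] - imp["importance"].mean()) \
            / imp["importance"].std(ddof=1)
        assert z.max() < 3.5

    def test_dominant_predictor_ranks_first(self, small_table):
        table = small_table.copy()
        act_cols = [c for c in table.columns if c.startswith("act_")]
        signal = max(act_cols, key=lambda c: table[c].std())
        table["viability"] = table[signal]
        final = kv.fit_final_model(table, k=5,
                                   spec=kv.ModelSpec(family="random_forest",
                                                     n_features=5, trees=50,
                                                     seed=0),
                                   include_dose=False)
        imp = kv.importance(final.model, final.selected_features)
        assert imp["feature"].iloc[0] == signal

    def test_annotation_tags(self, small_bundle):
        ann = small_bundle.annotation
        from sklearn.ensemble import RandomForestRegressor
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        model = RandomForestRegressor(n_estimators=10, random_state=0).fit(X, y)
        prot = ann["protein"].iloc[0]
        names = ["act_" + prot, "exp_G0001", "act_UNKNOWN"]
        with pytest.warns(UserWarning, match="UNKNOWN"):
            df = kv.importance(model, names, annotation=ann)
        tags = dict(zip(df["feature"], df["tag"]))
        want = {"dark": "dark kinase", "light": "light kinase",
                "non-kinase": "non-kinase"}[ann["class"].iloc[0]]
        assert tags["act_" + prot] == want
        assert tags["exp_G0001"] == "expression"
        assert tags["act_UNKNOWN"] == "non-kinase"

    def test_unsupported_family_rejected(self):
        from sklearn.linear_model import LinearRegression
        model = LinearRegression().fit([[0.0], [1.0]], [0.0, 1.0])
        with pytest.raises(ValueError):
            kv.importance(model, ["f"])

    def test_planted_targets_beat_non_planted(self, small_bundle,
                                              small_table):
        """Planted target features carry the signal, so their importance
        ranks are better than non-planted inhibition features."""
        final = kv.fit_final_model(small_table, k=40,
                                   spec=kv.ModelSpec(family="random_forest",
                                                     n_features=40, trees=60,
                                                     seed=0))
        names = final.selected_features + ["log10_dose"]
        imp = kv.importance(final.model, names)
        all_act = [c for c in small_table.columns if c.startswith("act_")]
        missing = [f for f in all_act if f not in set(imp["feature"])]
        extra = pd.DataFrame({"feature": missing, "importance": 0.0,
                              "tag": "other",
                              "rank": len(imp) + np.arange(len(missing)) + 1})
        imp = pd.concat([imp, extra], ignore_index=True)
        planted = {"act_" + p
                   for ps in small_bundle.truth.target_sets.values()
                   for p in ps}
        assert planted_importance_rank_test(imp, planted) < 0.01


class TestAblation:
    def test_expression_only_near_floor(self, small_table, small_folds):
        """Expression is dose-invariant; without inhibition features (and
        hence without the dose covariate) R^2 collapses."""
        res = kv.ablation_run(small_table, small_folds,
                              [{"classes": ("expression",), "k": 20,
                                "trees": 40}])
        assert res["r2"].iloc[0] < 0.1

    def test_kinase_only_restriction(self, small_table, small_folds,
                                     small_bundle):
        ann = small_bundle.annotation
        res = kv.ablation_run(small_table, small_folds,
                              [{"classes": ("inhibition", "expression"),
                                "k": 20, "trees": 40, "kinase_only": True}],
                              annotation=ann)
        assert 0.0 <= res["r2"].iloc[0] <= 1.0

    def test_single_dose_restricts_rows(self, small_table, small_folds):
        res = kv.ablation_run(small_table, small_folds,
                              [{"classes": ("inhibition", "expression"),
                                "k": 20, "trees": 40, "single_dose": True}])
        assert len(res) == 1

    def test_empty_feature_set_rejected(self, small_table, small_folds):
        with pytest.raises(ValueError, match="empty"):
            kv.ablation_run(
                small_table.drop(columns=[c for c in small_table.columns
                                          if c.startswith("exp_")]),
                small_folds,
                [{"classes": ("expression",), "k": 5}])
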