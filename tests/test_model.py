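"""Scoring conventions, the cross-validation contract, and the learner
benchmark."""

import numpy as np
import pandas as pd
import pytest

from brewlink import (
    LearnerSpec,
    MetabolitePredictor,
    assemble_features,
    coefficient_of_determination,
    compare_learners,
    cross_validated_predict,
    explained_variance,
)


class TestScores:
    def test_explained_variance_closed_forms(self):
        y = np.array([1.0, 2.0, 3.0])
        assert explained_variance(y, y) == pytest.approx(1.0)
        assert explained_variance(y, np.full(3, y.mean())) == pytest.approx(0.0)
        # Var({0,0,-1})/Var({1,2,3}) = (1/3)/1
        assert explained_variance(y, np.array([1.0, 2.0, 4.0])) == pytest.approx(2 / 3)

    def test_r_squared_closed_forms(self):
        y = np.array([1.0, 2.0, 3.0])
        assert coefficient_of_determination(y, y) == pytest.approx(1.0)
        assert coefficient_of_determination(y, np.full(3, 2.0)) == pytest.approx(0.0)
        assert coefficient_of_determination(y, np.array([3.0, 2.0, 1.0])) < 0

    def test_agree_when_residual_mean_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        resid = rng.normal(size=50)
        resid -= resid.mean()
        assert explained_variance(y, y - resid) == pytest.approx(
            coefficient_of_determination(y, y - resid), abs=1e-9
        )

    def test_matches_sklearn_convention(self):
        from sklearn.metrics import explained_variance_score, r2_score

        rng = np.random.default_rng(1)
        y, yhat = rng.normal(size=30), rng.normal(size=30)
        assert explained_variance(y, yhat) == pytest.approx(explained_variance_score(y, yhat))
        assert coefficient_of_determination(y, yhat) == pytest.approx(r2_score(y, yhat))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            explained_variance(np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            coefficient_of_determination(np.ones(5), np.zeros(5))
        with pytest.raises(ValueError):
            explained_variance(np.ones(3), np.ones(4))


class TestCrossValidatedPredict:
    def test_noiseless_linear_lasso_recovers(self, noiseless_prep):
        X = assemble_features("FM", noiseless_prep)
        res = cross_validated_predict(X, noiseless_prep.metabolites["m01"], "lasso", seed=0)
        assert res.explained_variance >= 0.99

    def test_oof_covers_every_sample_once(self, noiseless_prep):
        X = assemble_features("PI", noiseless_prep)
        res = cross_validated_predict(X, noiseless_prep.metabolites["m03"], "lasso", seed=1)
        assert res.oof.index.equals(noiseless_prep.metabolites.index)
        assert res.oof.notna().all()
        covered = np.concatenate([fm.test_index for fm in res.fold_models])
        assert sorted(covered) == list(range(len(res.oof)))

    def test_deterministic_given_seed(self, noiseless_prep):
        X = assemble_features("PI", noiseless_prep)
        y = noiseless_prep.metabolites["m01"]
        a = cross_validated_predict(X, y, "lasso", seed=7)
        b = cross_validated_predict(X, y, "lasso", seed=7)
        pd.testing.assert_series_equal(a.oof, b.oof)
        c = cross_validated_predict(X, y, "lasso", seed=8)
        assert not c.oof.equals(a.oof)

    def test_pure_noise_scores_near_zero(self, small_prep):
        X = assemble_features("AMS", small_prep)
        evs = [
            cross_validated_predict(X, small_prep.metabolites[m], "lasso", seed=s).explained_variance
            for s in range(3)
            for m in ("m01", "m02")
        ]
        assert np.median(evs) <= 0.1
        assert max(evs) <= 0.3

    def test_error_cases(self, small_prep):
        X = assemble_features("PI", small_prep)
        y = small_prep.metabolites["m01"]
        with pytest.raises(ValueError, match="folds exceed"):
            cross_validated_predict(X, y, "lasso", k=100)
        with pytest.raises(ValueError, match="constant"):
            cross_validated_predict(X, pd.Series(1.0, index=X.index), "lasso")
        with pytest.raises(ValueError, match="missing"):
            ybad = y.copy()
            ybad.iloc[0] = np.nan
            cross_validated_predict(X, ybad, "lasso")


class TestMetabolitePredictor:
    def test_fit_runs_and_summary(self, noiseless_prep):
        X = assemble_features("PI", noiseless_prep)
        res = MetabolitePredictor(X, noiseless_prep.metabolites["m01"], "lasso").fit(
            runs=3, seed=0
        )
        assert len(res.runs) == 3
        assert res.oof_predictions.shape == (len(X), 3)
        text = res.summary()
        assert "m01" in text and "lasso" in text and "explained variance" in text

    def test_from_tables_end_to_end(self, noiseless_cohort):
        tables, _ = noiseless_cohort
        pred = MetabolitePredictor.from_tables(tables, "m01", "PI", "lasso")
        res = pred.fit(seed=0)
        assert res.explained_variance_[0] > 0.9

    def test_run_seeds_differ_per_metabolite(self, noiseless_prep):
        X = assemble_features("PI", noiseless_prep)
        res1 = MetabolitePredictor(X, noiseless_prep.metabolites["m01"], "lasso").fit(seed=0)
        res3 = MetabolitePredictor(X, noiseless_prep.metabolites["m03"], "lasso").fit(seed=0)
        folds1 = [sorted(fm.test_index.tolist()) for fm in res1.runs[0].fold_models]
        folds3 = [sorted(fm.test_index.tolist()) for fm in res3.runs[0].fold_models]
        assert folds1 != folds3


def test_fm_dominates_pi_for_microbial_metabolite():
    """Nesting monotonicity: for a taxon-driven metabolite the full model's
    median EV over seeds is at least the physiochemical-only median."""
    from brewlink import PlantedEffect, SimConfig, generate_dataset, preprocess_study

    evs = {"FM": [], "PI": []}
    for seed in range(20):
        cfg = SimConfig(
            seed=seed,
            noise_sd=0.2,
            censor_quantile=0.0,
            effect_table=[PlantedEffect("m01", "taxon:sp002", "linear", 1.0)],
            n_metabolites=2,
        )
        tables, _ = generate_dataset(cfg)
        prep = preprocess_study(tables)
        for g in evs:
            X = assemble_features(g, prep)
            evs[g].append(
                cross_validated_predict(X, prep.metabolites["m01"], "lasso", seed=seed).explained_variance
            )
    assert np.median(evs["FM"]) >= np.median(evs["PI"])


def test_gini_criterion_resolves_to_squared_error():
    """Gini splitting only exists for classification; a forest configured
    with it must fall back to squared-error regression splits."""
    from brewlink.learners import build_estimator

    spec = LearnerSpec("random_forest", params={"criterion": "Gini"}, search_iterations=0)
    est = build_estimator(spec, n_features=5, random_state=0)
    assert est.criterion == "squared_error"


def test_compare_learners_paired_and_counted(small_prep):
    X = assemble_features("PI", small_prep)
    mets = small_prep.metabolites[["m01", "m02"]]
    lasso = LearnerSpec("lasso", search_iterations=0)
    rf = LearnerSpec("random_forest", params={"n_estimators": 20}, search_iterations=0)
    comp = compare_learners(X, mets, [lasso, rf], runs=2, seed=0)
    assert comp.counts_r2.shape == (2, 2)
    assert set(comp.counts_r2.index) == {"lasso", "random_forest"}
    assert ((comp.counts_r2 >= 0) & (comp.counts_r2 <= 2)).all().all()
    assert len(comp.scores) == 2 * 2 * 2
    assert "random_forest" in comp.summary()
    delta = comp.delta("random_forest", "lasso")
    assert set(delta.index) == {"m01", "m02"}
    with pytest.raises(ValueError, match="at least 2"):
        compare_learners(X, mets, [lasso], runs=1)
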