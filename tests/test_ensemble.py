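"""Preprocessing, the eight-model groups, and the weighted mean-probabilities combiner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tapdyn.ensemble import (
    MODEL_ROSTER,
    CombinedProbability,
    EnsembleConfig,
    combine_probabilities,
    fit_ensemble,
    fit_preprocess,
    load_model,
    predict,
    save_model,
)
from tapdyn.features import FEATURE_NAMES, HOLD_FEATURES

from conftest import random_feature_frame


class TestPreprocess:
    def test_minmax_scales_training_columns_to_unit_interval(self):
        rng = np.random.default_rng(0)
        X, y = random_feature_frame(rng, n_per_class=3)
        X["hold_L_mean"] = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
        state = fit_preprocess(X, y)
        scaled = state.hold_pipeline[:2].transform(
            X.loc[:, list(HOLD_FEATURES)].to_numpy(float)
        )
        col = list(HOLD_FEATURES).index("hold_L_mean")
        assert scaled[:, col] == pytest.approx([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0

    def test_imputation_is_identity_without_missing_values(self):
        rng = np.random.default_rng(1)
        X, y = random_feature_frame(rng, n_per_class=3)
        state = fit_preprocess(X, y)
        raw = X.loc[:, list(HOLD_FEATURES)].to_numpy(float)
        imputed = state.hold_pipeline["impute"].transform(raw)
        np.testing.assert_array_equal(imputed, raw)

    def test_missing_values_filled_with_training_means(self):
        rng = np.random.default_rng(2)
        X, y = random_feature_frame(rng, n_per_class=4)
        train_mean = X["hold_R_sd"].iloc[1:].mean()
        X.iloc[0, X.columns.get_loc("hold_R_sd")] = np.nan
        state = fit_preprocess(X, y)
        imputed = state.hold_pipeline["impute"].transform(
            X.loc[:, list(HOLD_FEATURES)].to_numpy(float)
        )
        col = list(HOLD_FEATURES).index("hold_R_sd")
        assert imputed[0, col] == pytest.approx(train_mean)

    def test_constant_feature_warns(self):
        rng = np.random.default_rng(3)
        X, y = random_feature_frame(rng, n_per_class=3)
        X["latency_LL_kurt"] = 5.0
        with pytest.warns(UserWarning, match="latency_LL_kurt"):
            fit_preprocess(X, y)

    def test_lda_direction_matches_closed_form(self):
        # two well-separated Gaussians: LDA weights align with pooled-cov^-1 (mu1 - mu0)
        rng = np.random.default_rng(4)
        X, y = random_feature_frame(rng, n_per_class=40, separation=4.0)
        state = fit_preprocess(X, y)
        scaled = state.hold_pipeline[:2].transform(
            X.loc[:, list(HOLD_FEATURES)].to_numpy(float)
        )
        mu0, mu1 = scaled[y == 0].mean(axis=0), scaled[y == 1].mean(axis=0)
        pooled = (
            np.cov(scaled[y == 0], rowvar=False) * (sum(y == 0) - 1)
            + np.cov(scaled[y == 1], rowvar=False) * (sum(y == 1) - 1)
        ) / (len(y) - 2)
        w_ref = np.linalg.solve(pooled, mu1 - mu0)
        w_lda = np.asarray(state.hold_pipeline["lda"].coef_).ravel()
        cos = abs(w_ref @ w_lda) / (np.linalg.norm(w_ref) * np.linalg.norm(w_lda))
        assert cos > 0.99
        proj = state.hold_pipeline.transform(X.loc[:, list(HOLD_FEATURES)].to_numpy(float))
        assert proj[y == 1].mean() - proj[y == 0].mean() > 2.0  # clear margin


class TestCombineRule:
    def test_all_half_is_fixed_point(self):
        c = combine_probabilities([0.5] * 8, [0.5] * 8, weight=1.2)
        assert c.value == pytest.approx(0.5, abs=1e-15)
        assert not c.clamped

    def test_mixed_worked_example(self):
        c = combine_probabilities([0.6] * 8, [0.7] * 8, weight=1.2)
        assert c.value == pytest.approx(0.67, abs=1e-12)

    def test_all_ones_clamps_from_1_05(self):
        c = combine_probabilities([1.0] * 8, [1.0] * 8, weight=1.2)
        assert c.raw == pytest.approx(1.05, abs=1e-12)
        assert c.value == 1.0 and c.clamped

    def test_all_zeros_clamps_from_below(self):
        c = combine_probabilities([0.0] * 8, [0.0] * 8, weight=1.2)
        assert c.raw == pytest.approx(-0.05, abs=1e-12)
        assert c.value == 0.0 and c.clamped

    @pytest.mark.parametrize(
        "hold,latency,weight",
        [([1.2] * 8, [0.5] * 8, 1.2), ([0.5] * 8, [-0.1] * 8, 1.2),
         ([0.5] * 8, [0.5] * 7, 1.2), ([], [], 1.2), ([0.5] * 8, [0.5] * 8, 0.0)],
    )
    def test_invalid_inputs_rejected(self, hold, latency, weight):
        with pytest.raises(ValueError):
            combine_probabilities(hold, latency, weight=weight)

    @given(st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
           st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8))
    def test_unit_weight_reduces_to_plain_mean(self, hold, latency):
        c = combine_probabilities(hold, latency, weight=1.0)
        assert c.raw == pytest.approx(np.mean(hold + latency), abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
           st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
           st.integers(0, 15), st.floats(0.01, 0.3))
    def test_monotone_in_every_probability(self, hold, latency, idx, delta):
        base = combine_probabilities(hold, latency, weight=1.2)
        bumped_h, bumped_l = list(hold), list(latency)
        if idx < 8:
            bumped_h[idx] = min(1.0, bumped_h[idx] + delta)
        else:
            bumped_l[idx - 8] = min(1.0, bumped_l[idx - 8] + delta)
        bumped = combine_probabilities(bumped_h, bumped_l, weight=1.2)
        assert bumped.value >= base.value - 1e-12


class TestEnsembleFit:
    def test_separable_training_set_classified_perfectly(self):
        rng = np.random.default_rng(5)
        X, y = random_feature_frame(rng, n_per_class=10, separation=6.0)
        model = fit_ensemble(X, y, EnsembleConfig(seed=0))
        results = predict(model, X)
        assert [int(r.label) for r in results] == list(y)
        assert all(len(r.hold_probs) == 8 and len(r.latency_probs) == 8 for r in results)
        assert set(results[0].hold_probs) == set(MODEL_ROSTER)

    def test_refit_same_seed_reproduces_probabilities(self):
        rng = np.random.default_rng(6)
        X, y = random_feature_frame(rng, n_per_class=8, separation=2.0)
        r1 = predict(fit_ensemble(X, y, EnsembleConfig(seed=3)), X)
        r2 = predict(fit_ensemble(X, y, EnsembleConfig(seed=3)), X)
        for a, b in zip(r1, r2):
            assert a.hold_probs == b.hold_probs
            assert a.latency_probs == b.latency_probs
            assert a.p_pd == b.p_pd

    def test_identical_labels_rejected(self):
        rng = np.random.default_rng(7)
        X, _ = random_feature_frame(rng, n_per_class=5)
        with pytest.raises(ValueError, match="identical"):
            fit_ensemble(X, np.zeros(10, dtype=int))

    def test_singleton_class_rejected_by_name(self):
        rng = np.random.default_rng(8)
        X, y = random_feature_frame(rng, n_per_class=5)
        y = y.copy()
        y[:] = 0
        y[-1] = 1
        with pytest.raises(ValueError, match="class 1"):
            fit_ensemble(X, y)

    def test_label_follows_inclusive_threshold(self):
        rng = np.random.default_rng(9)
        X, y = random_feature_frame(rng, n_per_class=4)
        model = fit_ensemble(X, y, EnsembleConfig(seed=0))

        class _Half:
            classes_ = np.array([0, 1])

            def predict_proba(self, Z):
                return np.full((len(Z), 2), 0.5)

        model.hold_models = {k: _Half() for k in MODEL_ROSTER}
        model.latency_models = {k: _Half() for k in MODEL_ROSTER}
        res = predict(model, X.iloc[:1])[0]
        assert res.p_pd == 0.5 and res.label is True

    def test_labels_consistent_with_threshold_everywhere(self):
        rng = np.random.default_rng(10)
        X, y = random_feature_frame(rng, n_per_class=8, separation=1.0)
        model = fit_ensemble(X, y)
        for r in predict(model, X):
            assert r.label == (r.p_pd >= 0.5)
            assert 0.0 <= r.p_pd <= 1.0

    def test_all_missing_row_scored_from_imputation_and_flagged(self):
        rng = np.random.default_rng(11)
        X, y = random_feature_frame(rng, n_per_class=6, separation=3.0)
        model = fit_ensemble(X, y)
        blank = pd.DataFrame(
            [[np.nan] * len(FEATURE_NAMES)], columns=list(FEATURE_NAMES), index=["blanksubj"]
        )
        (res,) = predict(model, blank)
        assert res.all_missing
        assert 0.0 <= res.p_pd <= 1.0

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        X, y = random_feature_frame(rng, n_per_class=5, separation=3.0)
        model = fit_ensemble(X, y, EnsembleConfig(seed=1))
        save_model(model, tmp_path / "model.joblib")
        back = load_model(tmp_path / "model.joblib")
        a = predict(model, X)
        b = predict(back, X)
        assert [r.p_pd for r in a] == [r.p_pd for r in b]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EnsembleConfig(weight=0.0)
        with pytest.raises(ValueError):
            EnsembleConfig(threshold=1.5)
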