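"""Split/CV/tuning machinery, basis expansion, scoring, persistence."""

import numpy as np
import pandas as pd
import pytest

from fiberspec.channels import BIOMARKERS
from fiberspec.errors import InputError, ParameterError, StateError
from fiberspec.regress import (
    FeatureBasis,
    RegressionBundle,
    predict,
    score,
    split_train_test,
    tune_and_train,
)


def _linear_toy(n=120, seed=0, noise=0.0):
    """Raw-column dataset (no *_height names -> basis passes through)."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    Y = pd.DataFrame({
        biomarker: (X @ w).to_numpy() + rng.normal(0, noise, n)
        for biomarker, w in zip(
            BIOMARKERS,
            ([1, 0, 0], [0, 2, 0], [0, 0, -1],
             [1, 1, 0], [2, 0, 1], [1, -1, 1]))
    })
    return X, Y


class TestSplit:
    def test_75_25_split_counts(self):
        train, test = split_train_test(list(range(100)), 0.75, seed=1)
        assert len(train) == 75 and len(test) == 25

    def test_same_seed_same_split(self):
        a = split_train_test(list(range(40)), 0.75, seed=9)
        b = split_train_test(list(range(40)), 0.75, seed=9)
        assert a == b

    def test_disjoint_and_exhaustive(self):
        data = list(range(57))
        train, test = split_train_test(data, 0.6, seed=2)
        assert sorted(train + test) == data
        assert not set(train) & set(test)

    def test_bad_fraction_and_tiny_dataset_rejected(self):
        with pytest.raises(ParameterError):
            split_train_test(list(range(20)), 1.2)
        with pytest.raises(InputError):
            split_train_test([1, 2, 3], 0.75)


class TestTuneAndTrain:
    def test_zero_penalty_ridge_recovers_linear_model(self):
        X, Y = _linear_toy(noise=0.0)
        bundle = tune_and_train(X, Y, family="ridge", grid=[0.0], folds=5)
        for b in BIOMARKERS:
            assert np.all(np.asarray(bundle.models[b].cv_r2) >
                          1 - 1e-9)
        pred = bundle.predict_frame(X)
        np.testing.assert_allclose(pred.to_numpy(), Y.to_numpy(), atol=1e-8)

    def test_lasso_shrinks_pure_noise_feature_to_zero(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"signal": rng.normal(size=200),
                          "junk": rng.normal(size=200)})
        Y = pd.DataFrame({b: X["signal"].to_numpy() for b in BIOMARKERS})
        bundle = tune_and_train(X, Y, family="lasso", grid=[0.5], folds=5)
        j = bundle.basis_names.index("junk")
        for b in BIOMARKERS:
            assert bundle.models[b].coef[j] == pytest.approx(0.0, abs=1e-12)

    def test_fold_scores_recorded(self):
        X, Y = _linear_toy(noise=0.1)
        bundle = tune_and_train(X, Y, family="bayesian", folds=4)
        for b in BIOMARKERS:
            assert len(bundle.models[b].cv_mse) == 4
            assert len(bundle.models[b].cv_mae) == 4

    def test_invalid_folds_rejected(self):
        X, Y = _linear_toy(n=20)
        with pytest.raises(ParameterError):
            tune_and_train(X, Y, family="ridge", folds=1)
        with pytest.raises(ParameterError):
            tune_and_train(X, Y, family="ridge", folds=30)

    def test_unknown_family_rejected(self):
        X, Y = _linear_toy(n=20)
        with pytest.raises(ParameterError):
            tune_and_train(X, Y, family="random_forest", folds=2)


class TestBasis:
    def test_height_columns_get_reciprocal_and_log_terms(self):
        X = pd.DataFrame({"sodium_height": [1.0, 2.0, 4.0],
                          "sodium_area": [1.0, 1.0, 1.0]})
        basis = FeatureBasis(degree=2, uni_degree=2)
        mat, names = basis.expand(X)
        assert "inv(sodium_height)" in names
        assert "log(sodium_height)" in names
        assert "sodium_area" in names  # raw passthrough
        col = names.index("inv(sodium_height)")
        np.testing.assert_allclose(mat[:, col], [1.0, 0.5, 0.25])

    def test_laser_groups_cross_terms(self):
        X = pd.DataFrame({
            "pH_height": [1.0, 2.0], "glucose_height": [3.0, 4.0],
            "calcium_height": [5.0, 6.0],
        })
        _, names = FeatureBasis(degree=2).expand(X)
        assert any("pH_height" in n and "glucose_height" in n for n in names)
        # calcium (520 nm) never crosses the 405 nm channels
        assert not any("calcium_height" in n and "pH_height" in n
                       for n in names)

    def test_expansion_is_deterministic(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.uniform(1, 2, size=(10, 2)),
                         columns=["pH_height", "glucose_height"])
        m1, n1 = FeatureBasis().expand(X)
        m2, n2 = FeatureBasis().expand(X)
        assert n1 == n2
        np.testing.assert_array_equal(m1, m2)


class TestPredictScore:
    def test_predictions_preserve_order_and_count(self):
        X, Y = _linear_toy(noise=0.05)
        bundle = tune_and_train(X, Y, family="ridge", grid=[1e-4], folds=4)
        result = predict(bundle, X)
        assert result.values.shape == (len(X), 6)
        np.testing.assert_array_equal(result.values.index, X.index)

    def test_uncorrected_features_rejected(self, channels, ref_state,
                                           noiseless):
        from fiberspec.features import extract_features
        from fiberspec.preprocess import PreprocessPipeline
        from fiberspec.sim import Simulator
        sim = Simulator(noise=noiseless)
        merged = PreprocessPipeline().process_scan(sim.run_scan(ref_state))
        fv = extract_features(merged, channels)  # not corrected
        X, Y = _linear_toy(noise=0.05)
        bundle = tune_and_train(X, Y, family="ridge", grid=[1e-4], folds=4)
        with pytest.raises(StateError):
            predict(bundle, fv)

    def test_out_of_range_predictions_flagged(self):
        X, Y = _linear_toy(noise=0.0)
        Y = Y * 0 + 1000.0  # constant far outside every admissible range
        bundle = tune_and_train(X, Y, family="ridge", grid=[1e-4], folds=4)
        result = predict(bundle, X)
        assert result.out_of_range.to_numpy().all()

    def test_perfect_predictions_score_zero_error(self):
        Y = pd.DataFrame({b: np.arange(5.0) for b in BIOMARKERS})
        table = score(Y, Y)
        assert (table["mse"] == 0).all()
        assert (table["mae"] == 0).all()
        assert (table["r2"] == 1).all()

    def test_hand_computed_mse_mae(self):
        table = score(pd.DataFrame({"x": [2.0, 4.0]}),
                      pd.DataFrame({"x": [1.0, 2.0]}))
        assert table.loc["x", "mse"] == pytest.approx(2.5)
        assert table.loc["x", "mae"] == pytest.approx(1.5)

    def test_shuffled_predictions_have_nonpositive_r2(self):
        rng = np.random.default_rng(4)
        truth = rng.normal(size=2000)
        shuffled = rng.permutation(truth)
        table = score(pd.DataFrame({"x": shuffled}),
                      pd.DataFrame({"x": truth}))
        assert table.loc["x", "r2"] < 0.1

    def test_constant_truth_r2_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning):
            table = score(pd.DataFrame({"x": [1.0, 2.0]}),
                          pd.DataFrame({"x": [3.0, 3.0]}))
        assert np.isnan(table.loc["x", "r2"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            score(pd.DataFrame({"x": [1.0]}),
                  pd.DataFrame({"x": [1.0, 2.0]}))


class TestRecoveryInvariants:
    def test_noiseless_sweep_heldout_r2_at_least_0_99_all_six(
            self, trained_noiseless):
        assert (trained_noiseless.test_scores["r2"] >= 0.99).all(), \
            trained_noiseless.test_scores

    def test_overlapped_ph_glucose_resolved_at_default_noise(
            self, trained_default):
        # pH (idx 34) and glucose (idx 28) vary simultaneously in the
        # factorial set with near-total peak overlap at FWHM 30
        assert trained_default.test_scores.loc["pH", "r2"] >= 0.9
        assert trained_default.test_scores.loc["glucose", "r2"] >= 0.9

    def test_do_and_glucose_residuals_do_not_trend_with_temperature(
            self, trained_default):
        bundle = trained_default.bundle
        X = trained_default.features[bundle.feature_names]
        pred = bundle.predict_frame(X)
        truth = trained_default.labels
        for b in ("dissolved_oxygen", "glucose"):
            resid = pred[b].to_numpy() - truth[b].to_numpy()
            r = np.corrcoef(resid, truth["temperature"].to_numpy())[0, 1]
            assert abs(r) < 0.2, f"{b}: corr(residual, T) = {r:.3f}"


def test_bundle_json_round_trip_predicts_identically(tmp_path):
    X, Y = _linear_toy(noise=0.05)
    bundle = tune_and_train(X, Y, family="bayesian", folds=4)
    path = tmp_path / "model.json"
    bundle.save(path)
    loaded = RegressionBundle.load(path)
    np.testing.assert_allclose(loaded.predict_frame(X).to_numpy(),
                               bundle.predict_frame(X).to_numpy(),
                               rtol=1e-12)
    assert loaded.family == "bayesian"
    assert loaded.models["pH"].penalty is None
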