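"""Random-forest determinants: CV metrics, importance, partial dependence."""

import numpy as np
import pandas as pd
import pytest

from deapanel.determinants import (
    RFConfig,
    fit_regional,
    fit_rf,
    partial_dependence,
    perturbation_importance,
)

SMALL = dict(n_trees=100, vars_per_split=3, cv_folds=5, cv_repeats=1,
             n_importance_subsamples=30, n_pd_observations=200)


def make_linear_data(seed, n=400, k=5, signal=5.0):
    """x1 dominates the target; remaining features are independent noise."""
    r = np.random.default_rng(seed)
    X = pd.DataFrame(
        {f"x{i + 1}": r.normal(size=n) for i in range(k)}
    )
    y = signal * X["x1"].to_numpy() + r.normal(scale=0.5, size=n)
    return X, y


class TestFitRF:
    def test_constant_target_rejected(self):
        X, _ = make_linear_data(0)
        with pytest.raises(ValueError, match="constant target"):
            fit_rf(X, np.ones(len(X)), RFConfig(**SMALL, seed=0))

    def test_missing_values_rejected(self):
        X, y = make_linear_data(0)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_rf(X, y, RFConfig(**SMALL, seed=0))

    def test_strong_signal_gives_high_cv_r2(self):
        X, y = make_linear_data(11)
        _, metrics = fit_rf(X, y, RFConfig(**SMALL, seed=11))
        assert metrics.r_squared >= 0.7
        assert metrics.rmse == pytest.approx(np.sqrt(metrics.mse), abs=1e-9)
        assert metrics.mad <= metrics.rmse

    def test_pure_noise_target_has_no_skill(self):
        r = np.random.default_rng(13)
        X = pd.DataFrame({f"x{i}": r.normal(size=300) for i in range(4)})
        y = r.normal(size=300)
        _, metrics = fit_rf(X, y, RFConfig(**SMALL, seed=13))
        assert metrics.r_squared <= 0.1

    def test_fewer_rows_than_folds_rejected(self):
        X, y = make_linear_data(0, n=4)
        with pytest.raises(ValueError, match="fewer than cv_folds"):
            fit_rf(X, y, RFConfig(**SMALL, seed=0))


@pytest.fixture(scope="module")
def fitted():
    X, y = make_linear_data(17)
    cfg = RFConfig(**SMALL, seed=17)
    model, _ = fit_rf(X, y, cfg)
    return model, X, y, cfg


class TestPerturbationImportance:
    def test_dominant_predictor_ranks_first(self, fitted):
        model, X, y, cfg = fitted
        table = perturbation_importance(model, X, y, cfg)
        assert table.iloc[0]["variable"] == "x1"
        assert list(table["rank"]) == list(range(1, len(X.columns) + 1))

    def test_noise_feature_importance_near_zero(self, fitted):
        model, X, y, cfg = fitted
        table = perturbation_importance(model, X, y, cfg).set_index("variable")
        for var in ("x3", "x4", "x5"):
            row = table.loc[var]
            assert abs(row.mean_delta_rmse) <= 2 * row.sd_delta_rmse

    def test_seeded_determinism(self, fitted):
        model, X, y, cfg = fitted
        a = perturbation_importance(model, X, y, cfg,
                                    rng=np.random.default_rng(1))
        b = perturbation_importance(model, X, y, cfg,
                                    rng=np.random.default_rng(1))
        pd.testing.assert_frame_equal(a, b)

    def test_feature_mismatch_rejected(self, fitted):
        model, X, y, cfg = fitted
        with pytest.raises(ValueError, match="feature mismatch"):
            perturbation_importance(model, X.rename(columns={"x1": "z"}), y, cfg)


class TestPartialDependence:
    def test_constant_model_gives_flat_curve(self):
        X, _ = make_linear_data(3, n=200)
        y = np.full(len(X), 0.5)
        y[0] = 0.5 + 1e-9  # dodge the constant-target guard, fit is still flat
        cfg = RFConfig(**SMALL, seed=3)
        model, _ = fit_rf(X, y, cfg)
        curve = partial_dependence(model, X, "x1", cfg)
        assert np.ptp(curve.mean_prediction) < 1e-6

    def test_monotone_signal_gives_monotone_curve(self):
        X, y = make_linear_data(19)
        cfg = RFConfig(**SMALL, seed=19)
        model, _ = fit_rf(X, y, cfg)
        curve = partial_dependence(model, X, "x1", cfg)
        assert (np.diff(curve.mean_prediction) >= -1e-9).all()
        assert (np.diff(curve.grid) > 0).all()

    def test_seeded_determinism(self):
        X, y = make_linear_data(5)
        cfg = RFConfig(**SMALL, seed=5)
        model, _ = fit_rf(X, y, cfg)
        a = partial_dependence(model, X, "x2", cfg, rng=np.random.default_rng(2))
        b = partial_dependence(model, X, "x2", cfg, rng=np.random.default_rng(2))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_variable_rejected(self):
        X, y = make_linear_data(5)
        cfg = RFConfig(**SMALL, seed=5)
        model, _ = fit_rf(X, y, cfg)
        with pytest.raises(ValueError, match="not a model feature"):
            partial_dependence(model, X, "nope", cfg)


class TestFitRegional:
    def test_region_specific_signal_recovered_and_small_region_skipped(self):
        r = np.random.default_rng(19)
        n_per = 250
        frames, targets, regions = [], [], []
        for reg, dominant in [(1, "x1"), (2, "x2")]:
            X = pd.DataFrame({f"x{i + 1}": r.normal(size=n_per) for i in range(4)})
            y = 4.0 * X[dominant].to_numpy() + r.normal(scale=0.5, size=n_per)
            frames.append(X)
            targets.append(y)
            regions.append(np.full(n_per, reg))
        # region 3 is under-populated and must be skipped
        frames.append(pd.DataFrame({f"x{i + 1}": r.normal(size=3) for i in range(4)}))
        targets.append(r.normal(size=3))
        regions.append(np.full(3, 3))
        X = pd.concat(frames, ignore_index=True)
        y = np.concatenate(targets)
        reg = np.concatenate(regions)
        results, skipped = fit_regional(X, y, reg, RFConfig(**SMALL, seed=19))
        assert skipped == [3]
        assert results[1][1].iloc[0]["variable"] == "x1"
        assert results[2][1].iloc[0]["variable"] == "x2"
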