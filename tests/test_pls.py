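import numpy as np
import pytest

import tripepqsar as tq
from tripepqsar.pls import CVScheme, autoscale, fit_pls


def _random_instance(n, p, seed, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


def sklearn_loo_q2(X, y, max_components):
    """Independent LOO oracle: scikit-learn PLS refit from scratch per fold,
    with per-fold autoscaling, PRESS/TSS about the grand mean."""
    from sklearn.cross_decomposition import PLSRegression

    n, p = X.shape
    press = np.zeros(max_components)
    for c in range(1, max_components + 1):
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0, ddof=1)
            sd[sd < 1e-12] = np.inf
            Xs = (X[tr] - mu) / sd
            ym = y[tr].mean()
            m = PLSRegression(n_components=c, scale=False).fit(
                Xs, y[tr] - ym
            )
            pred = ym + float(
                np.ravel(m.predict(((X[i] - mu) / sd)[None, :]))[0]
            )
            press[c - 1] += (y[i] - pred) ** 2
    tss = ((y - y.mean()) ** 2).sum()
    return 1 - press / tss


class TestAutoscale:
    def test_unit_variance_zero_mean(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        y = np.array([1.0, 2.0, 4.0])
        Xs, yc, params = autoscale(X, y)
        np.testing.assert_allclose(Xs[:, 0].mean(), 0, atol=1e-12)
        np.testing.assert_allclose(Xs[:, 0].std(ddof=1), 1, atol=1e-12)
        np.testing.assert_allclose(yc.mean(), 0, atol=1e-12)

    def test_constant_column_flagged_and_zeroed(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        Xs, _, params = autoscale(X, np.arange(3.0))
        assert params.constant_columns.tolist() == [False, True]
        np.testing.assert_array_equal(Xs[:, 1], 0.0)

    def test_params_reproduce_training_transform(self):
        X, y = _random_instance(12, 4, seed=0)
        Xs, _, params = autoscale(X, y)
        np.testing.assert_allclose(params.apply(X), Xs)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            autoscale(np.ones((1, 3)), np.ones(1))


class TestFitPLS:
    def test_noiseless_full_rank_fit_is_exact(self):
        X, y = _random_instance(20, 5, seed=1, noise=0.0)
        model = fit_pls(X, y, n_components=5)
        assert model.r2 == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-6)

    def test_one_component_single_variable_equals_simple_regression(self):
        # closed-form least-squares slope/intercept oracle
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = 2.5 * x + 1.0 + 0.3 * rng.normal(size=15)
        model = fit_pls(x[:, None], y, n_components=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        assert model.coefficients[0] == pytest.approx(slope, rel=1e-10)
        assert model.intercept == pytest.approx(intercept, rel=1e-10)

    def test_max_components_equals_ols_on_full_rank_data(self):
        X, y = _random_instance(30, 4, seed=5)
        model = fit_pls(X, y, n_components=4)
        Z = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), Z @ beta, atol=1e-8)

    def test_matches_sklearn_coefficients(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_instance(25, 8, seed=7)
        Xs, yc, params = autoscale(X, y)
        for c in (1, 3, 6):
            ours = fit_pls(X, y, n_components=c)
            ref = PLSRegression(n_components=c, scale=False).fit(Xs, yc)
            np.testing.assert_allclose(
                ours.coef_scaled, ref.coef_.ravel(), atol=1e-8
            )

    def test_zero_variance_response_rejected(self):
        X, _ = _random_instance(10, 3, seed=0)
        with pytest.raises(ValueError, match="variance"):
            fit_pls(X, np.ones(10), 2)

    def test_out_of_range_components_rejected(self):
        X, y = _random_instance(10, 3, seed=0)
        with pytest.raises(ValueError):
            fit_pls(X, y, 0)
        with pytest.raises(ValueError):
            fit_pls(X, y, 4)


class TestCrossValidate:
    def test_loo_matches_brute_force_oracle(self):
        X, y = _random_instance(10, 4, seed=11)
        ours = tq.cross_validate(X, y, CVScheme(), 4)
        oracle = sklearn_loo_q2(X, y, 4)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_noiseless_linear_data_reaches_q2_one(self):
        X, y = _random_instance(25, 4, seed=2, noise=0.0)
        q2 = tq.cross_validate(X, y, CVScheme(), 4)
        assert q2[-1] > 0.9999

    def test_pure_noise_has_low_q2(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        q2 = tq.cross_validate(X, y, CVScheme(), 5)
        assert np.all(q2 < 0.3)

    def test_kfold_deterministic_given_seed(self):
        X, y = _random_instance(30, 6, seed=4)
        scheme = CVScheme(kind="kfold", k=5, seed=42)
        np.testing.assert_array_equal(
            tq.cross_validate(X, y, scheme, 4),
            tq.cross_validate(X, y, scheme, 4),
        )

    def test_global_scaling_mode_runs_and_differs(self):
        X, y = _random_instance(20, 6, seed=6)
        per_fold = tq.cross_validate(X, y, CVScheme(), 4)
        glob = tq.cross_validate(
            X, y, CVScheme(scaling_mode="global"), 4
        )
        assert per_fold.shape == glob.shape
        assert not np.allclose(per_fold, glob)

    def test_r2_nondecreasing_in_components(self):
        X, y = _random_instance(20, 6, seed=8)
        r2 = [fit_pls(X, y, c).r2 for c in range(1, 7)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_predictions_invariant_to_column_rescaling(self):
        X, y = _random_instance(18, 5, seed=9)
        model = fit_pls(X, y, 3)
        X2 = X.copy()
        X2[:, 2] = X2[:, 2] * 40.0 - 7.0
        model2 = fit_pls(X2, y, 3)
        np.testing.assert_allclose(
            model.predict(X), model2.predict(X2), atol=1e-9
        )


class TestSelectComponents:
    @pytest.mark.parametrize("curve,expected", [
        ([0.2, 0.5, 0.4], 2),
        ([0.5, 0.5], 1),          # tie -> fewer components
        ([-0.3, -0.1, -0.2], 2),
    ])
    def test_argmax_with_tie_toward_fewer(self, curve, expected):
        assert tq.select_components(curve) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            tq.select_components([])
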