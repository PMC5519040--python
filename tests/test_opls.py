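"""OPLS fitting, VIP scores, cross-validation and permutation validation."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from crgmet.opls import OPLSRegressor, cross_validate, permutation_test


def random_problem(rng, n=20, k=10, signal=False):
    X = rng.normal(size=(n, k))
    y = X[:, 0] + 0.1 * rng.normal(size=n) if signal else rng.normal(size=n)
    return X, y


class TestAgainstPls1Oracle:
    def test_no_orthogonal_components_reduces_to_pls1(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            X, y = random_problem(rng)
            ours = OPLSRegressor(n_ortho=0, random_state=0).fit(X, y)
            oracle = PLSRegression(n_components=1, scale=False).fit(X, y)
            np.testing.assert_allclose(ours.predict(X), oracle.predict(X).ravel(), atol=1e-10)

    def test_coefficients_reproduce_predictions(self):
        rng = np.random.default_rng(3)
        X, y = random_problem(rng, signal=True)
        m = OPLSRegressor(n_ortho=2, random_state=0).fit(X, y)
        manual = (X - m.x_mean_) @ m.coef_ + m.y_mean_
        np.testing.assert_allclose(m.predict(X), manual, atol=1e-10)


class TestVip:
    def test_weight_on_single_variable_concentrates_vip(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        yc = y - y.mean()
        # two distractors exactly orthogonal to the centered response
        z = rng.normal(size=(40, 2))
        z -= np.outer(yc, yc @ z) / (yc @ yc)
        X = np.column_stack([y, z])
        m = OPLSRegressor(n_ortho=0, random_state=0).fit(X, y)
        np.testing.assert_allclose(m.vip_, [np.sqrt(3), 0.0, 0.0], atol=1e-8)

    def test_mean_squared_vip_is_one_for_any_fit(self):
        rng = np.random.default_rng(11)
        for n_ortho in (0, 1, 3):
            X, y = random_problem(rng, n=30, k=17, signal=True)
            m = OPLSRegressor(n_ortho=n_ortho, random_state=0).fit(X, y)
            assert np.mean(m.vip_**2) == pytest.approx(1.0, abs=1e-8)
            m2 = OPLSRegressor(n_ortho=n_ortho, vip_mode="total", random_state=0).fit(X, y)
            assert np.mean(m2.vip_**2) == pytest.approx(1.0, abs=1e-8)


class TestOrthogonalFiltering:
    def test_predictive_scores_orthogonal_to_orthogonal_scores(self):
        rng = np.random.default_rng(5)
        X, y = random_problem(rng, n=30, k=12, signal=True)
        m = OPLSRegressor(n_ortho=3, random_state=0).fit(X, y)
        assert m.n_ortho_ >= 1
        for k in range(m.n_ortho_):
            t_o = m.T_ortho_[:, k]
            assert abs(m.t_ @ t_o) < 1e-8 * np.linalg.norm(m.t_) * np.linalg.norm(t_o)

    def test_deflation_strictly_removes_variance(self):
        rng = np.random.default_rng(6)
        X, y = random_problem(rng, n=30, k=12, signal=True)
        m = OPLSRegressor(n_ortho=1, random_state=0).fit(X, y)
        Xc = X - X.mean(axis=0)
        assert np.linalg.norm(m._core_["X_filtered"]) < np.linalg.norm(Xc)

    def test_orthogonal_component_absorbs_structured_nuisance(self):
        # X = [y, z] with z orthogonal to y and much larger variance: one
        # orthogonal component must absorb z, leaving the predictive
        # component aligned with y.
        rng = np.random.default_rng(8)
        y = rng.normal(size=50)
        z = rng.normal(size=50)
        z -= (z @ y) / (y @ y) * y
        X = np.column_stack([y, 10.0 * z])
        m = OPLSRegressor(n_ortho=1, random_state=0).fit(X, y)
        corr = np.corrcoef(m.t_, y - y.mean())[0, 1]
        assert abs(corr) > 0.999

    def test_perfect_single_predictor_approaches_r2_one(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=40)
        X = np.column_stack([y, 1e-6 * rng.normal(size=(40, 5))])
        m = OPLSRegressor(n_ortho=0, random_state=0).fit(X, y)
        assert m.r2y_ > 0.999999
        assert np.argmax(np.abs(m.w_)) == 0


class TestValidation:
    def test_noiseless_signal_gives_high_q2(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=48)
        X = np.column_stack([y, 0.01 * rng.normal(size=(48, 5))])
        q2, fold_rmse = cross_validate(X, y, n_ortho=0, n_folds=8, random_state=0)
        assert q2 > 0.99
        assert len(fold_rmse) == 8 and (fold_rmse >= 0).all()

    def test_null_data_gives_nonpositive_q2_on_average(self):
        rng = np.random.default_rng(2)
        q2s = []
        for seed in range(5):
            X, y = random_problem(rng, n=40, k=30)
            q2, _ = cross_validate(X, y, n_ortho=0, n_folds=8, random_state=seed)
            q2s.append(q2)
        assert np.mean(q2s) < 0

    def test_fixed_seed_reproduces_folds_and_q2(self):
        rng = np.random.default_rng(4)
        X, y = random_problem(rng, signal=True)
        a = cross_validate(X, y, n_ortho=0, n_folds=5, random_state=42)
        b = cross_validate(X, y, n_ortho=0, n_folds=5, random_state=42)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_permutation_p_small_for_strong_signal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(48, 30))
        y = X[:, 0] + 0.3 * rng.normal(size=48)
        report = permutation_test(X, y, n_perm=199, n_ortho=0, random_state=0)
        assert report.p_value <= 0.02
        assert 0 < report.p_value <= 1
        assert len(report.rmse_perm) == 199

    def test_permutation_test_rejects_degenerate_inputs(self):
        rng = np.random.default_rng(1)
        X, y = random_problem(rng)
        with pytest.raises(ValueError):
            permutation_test(X, y, n_perm=0, random_state=0)
        with pytest.warns(UserWarning):
            permutation_test(X, y, n_perm=20, random_state=0)


class TestInputValidation:
    def test_constant_response_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="constant"):
            OPLSRegressor(n_ortho=0).fit(X, np.ones(10))

    def test_zero_variance_column_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            OPLSRegressor(n_ortho=0).fit(X, rng.normal(size=10))

    def test_negative_n_ortho_rejected(self):
        rng = np.random.default_rng(0)
        X, y = random_problem(rng)
        with pytest.raises(ValueError):
            OPLSRegressor(n_ortho=-1).fit(X, y)

    def test_sklearn_params_roundtrip(self):
        m = OPLSRegressor(n_ortho=2, delta_q2=0.02)
        params = m.get_params()
        assert params["n_ortho"] == 2
        m.set_params(n_ortho="auto")
        assert m.n_ortho == "auto"


def test_auto_selection_follows_q2_improvement_contract():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(40, 25))
    y = X[:, 0] + 0.5 * rng.normal(size=40)
    m = OPLSRegressor(n_ortho="auto", random_state=0).fit(X, y)
    path = m.q2_path_
    # every accepted component improved Q2 by more than delta_q2 over the
    # previous best, and the reported Q2 is the selected component count's
    for k in range(1, m.n_ortho_ + 1):
        assert path[k] > max(path[:k]) + m.delta_q2
    assert m.q2_ == path[m.n_ortho_]
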