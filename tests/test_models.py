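"""The three regression families under the uniform fit/predict contract."""

import numpy as np
import pytest

from jumppower.models import (
    ModelParams,
    PeakPowerRegressor,
    baseline_flight_time_model,
    rmse,
)


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 4))
    y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 45.0
    return X, y


class TestRmse:
    def test_zero_for_identical(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_symmetric_unit_errors(self):
        assert rmse([1.0, -1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_matches_formula(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert rmse(a, b) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestLinearFamily:
    def test_vanishing_ridge_equals_ols(self, linear_data):
        X, y = linear_data
        m = PeakPowerRegressor(family="LR", lr_reg="Ridge",
                               lr_solver="Least Squares", lam_lr=1e-10).fit(X, y)
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(len(X)), X]), y, rcond=None
        )[0]
        pred_ols = np.column_stack([np.ones(len(X)), X]) @ beta
        np.testing.assert_allclose(m.predict(X), pred_ols, atol=1e-6)

    def test_standardisation_affine_invariance(self, linear_data):
        # least-squares is affine-equivariant: Z on/off gives identical
        # predictions on full-rank data
        X, y = linear_data
        y_noisy = y + np.random.default_rng(0).normal(0, 0.5, len(y))
        p_off = PeakPowerRegressor(family="LR", lam_lr=1e-12,
                                   standardize=False).fit(X, y_noisy).predict(X)
        p_on = PeakPowerRegressor(family="LR", lam_lr=1e-12,
                                  standardize=True).fit(X, y_noisy).predict(X)
        np.testing.assert_allclose(p_off, p_on, atol=1e-8)

    def test_scale_invariance_with_z(self, linear_data):
        X, y = linear_data
        m1 = PeakPowerRegressor(family="LR", lam_lr=1e-3, standardize=True)
        m2 = PeakPowerRegressor(family="LR", lam_lr=1e-3, standardize=True)
        p1 = m1.fit(X, y).predict(X)
        p2 = m2.fit(X * 37.0, y).predict(X * 37.0)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_lasso_and_sgd_solvers_run(self, linear_data):
        X, y = linear_data
        for reg in ("Ridge", "Lasso"):
            for solver in ("Least Squares", "SVM"):
                m = PeakPowerRegressor(family="LR", lr_reg=reg, lr_solver=solver,
                                       lam_lr=1e-6).fit(X, y)
                assert rmse(m.predict(X), y) < 0.5


class TestAllFamiliesOnLinearTruth:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="LR", lr_reg="Ridge", lam_lr=1e-10),
            dict(family="SVM", svm_kernel="Linear", box_constraint=1e3,
                 epsilon=1e-4, kernel_scale=1.0),
            dict(family="GPR", gpr_basis="Linear", gpr_kernel="Squared Exponential",
                 sigma=1e-4),
        ],
    )
    def test_near_zero_training_error(self, linear_data, kwargs):
        X, y = linear_data
        m = PeakPowerRegressor(**kwargs).fit(X, y)
        tol = 1e-3 if kwargs["family"] != "SVM" else 1e-3 + kwargs["epsilon"]
        assert rmse(m.predict(X), y) <= tol


class TestGPR:
    def test_huge_noise_shrinks_to_mean(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        y = 45.0 + 0.1 * rng.standard_normal(40)
        m = PeakPowerRegressor(family="GPR", gpr_basis="Constant",
                               sigma=100.0).fit(X, y)
        pred = m.predict(X)
        np.testing.assert_allclose(pred, y.mean(), atol=0.05)

    def test_tiny_noise_interpolates(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 2))
        y = np.sin(X[:, 0]) + 40.0
        m = PeakPowerRegressor(family="GPR", gpr_basis="None",
                               gpr_kernel="Matern 5/2", sigma=1e-4).fit(X, y)
        assert rmse(m.predict(X), y) < 1e-2

    @pytest.mark.parametrize("basis", ["None", "Constant", "Linear",
                                       "Pure Quadratic"])
    @pytest.mark.parametrize("kernel", ["Exponential", "Matern 3/2",
                                        "Rational Quadratic"])
    def test_all_bases_and_kernels_fit(self, basis, kernel):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + 45.0 + 0.1 * rng.standard_normal(30)
        m = PeakPowerRegressor(family="GPR", gpr_basis=basis, gpr_kernel=kernel,
                               sigma=0.1).fit(X, y)
        assert np.isfinite(m.predict(X)).all()


class TestContract:
    def test_duplicated_row_duplicated_prediction(self, linear_data):
        X, y = linear_data
        m = PeakPowerRegressor(family="SVM", svm_kernel="Gaussian",
                               box_constraint=10.0).fit(X, y)
        X2 = np.vstack([X[0], X[0]])
        p = m.predict(X2)
        assert p[0] == p[1]

    def test_row_order_invariance(self, linear_data):
        X, y = linear_data
        m = PeakPowerRegressor(family="GPR", sigma=0.1).fit(X, y)
        perm = np.random.default_rng(7).permutation(len(X))
        np.testing.assert_allclose(m.predict(X)[perm], m.predict(X[perm]),
                                   atol=1e-10)

    def test_dimension_mismatch_rejected(self, linear_data):
        X, y = linear_data
        m = PeakPowerRegressor(family="LR").fit(X, y)
        with pytest.raises(ValueError):
            m.predict(X[:, :2])

    def test_model_params_roundtrip(self):
        decoded = {"standardize": "No", "lr_reg": "Lasso",
                   "lr_solver": "Least Squares", "lam_lr": 0.01}
        p = ModelParams.from_decoded(decoded, "LR")
        assert p.lr_reg == "Lasso" and not p.standardize
        m = PeakPowerRegressor.from_params(p)
        assert m.family == "LR" and m.lam_lr == 0.01


class TestBaseline:
    def test_exact_linear_truth_near_zero_cv(self):
        rng = np.random.default_rng(8)
        flight = rng.uniform(0.3, 0.6, 80)
        mass = rng.uniform(50, 100, 80)
        y = 20.0 + 50.0 * flight + 0.1 * mass
        _, cv = baseline_flight_time_model(flight, mass, y, seed=1)
        assert cv < 1e-8

    def test_permuted_outcome_matches_sd(self):
        rng = np.random.default_rng(9)
        flight = rng.uniform(0.3, 0.6, 200)
        mass = rng.uniform(50, 100, 200)
        y = rng.normal(45, 7, 200)
        perm = rng.permutation(y)
        _, cv = baseline_flight_time_model(flight, mass, perm, seed=1)
        assert cv == pytest.approx(np.std(y), rel=0.15)

    def test_too_few_jumps_rejected(self):
        with pytest.raises(ValueError):
            baseline_flight_time_model([0.4] * 5, [70] * 5, [45] * 5)

    def test_collinear_rejected(self):
        flight = np.full(20, 0.48)
        mass = np.full(20, 70.0)
        with pytest.raises(ValueError):
            baseline_flight_time_model(flight, mass, np.arange(20.0))
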