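"""Regression model families with a uniform fit/predict contract.

Three families predict peak power (W/kg) from FPC scores:

* LR — regularised linear regression: ridge or lasso penalty, solved
  either by (regularised) least squares or by a linear epsilon-insensitive
  (SVM-style) formulation; penalty strength lambda_LR.
* SVM — epsilon-insensitive support vector regression with Gaussian,
  linear or polynomial (degree 3) kernels; box constraint BC, kernel scale
  KS and tube half-width epsilon.
* GPR — Gaussian process regression with an explicit mean basis (none /
  constant / linear / pure quadratic) and a choice of stationary kernels;
  the noise level sigma is fixed while kernel length scales are refined
  internally by marginal-likelihood maximisation.

Real-valued hyperparameters arrive on a linear scale (already
de-transformed from their log10 encoding).  With standardisation enabled,
predictors and outcome are z-scored on the training set and predictions
are mapped back to outcome units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    RationalQuadratic,
)
from sklearn.linear_model import Lasso, LinearRegression, Ridge, SGDRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVR
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .params import FAMILIES


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared error, W/kg."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if pred.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


@dataclass(frozen=True)
class ModelParams:
    """Resolved (linear-scale) hyperparameters for one model family."""

    family: str
    standardize: bool = False
    # LR
    lr_reg: str = "Ridge"
    lr_solver: str = "Least Squares"
    lam_lr: float = 1e-3
    # SVM
    svm_kernel: str = "Gaussian"
    box_constraint: float = 1.0
    kernel_scale: float = 1.0
    epsilon: float = 0.1
    # GPR
    gpr_basis: str = "Constant"
    gpr_kernel: str = "Matern 5/2"
    sigma: float = 0.1

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @classmethod
    def from_decoded(cls, decoded: dict, family: str) -> "ModelParams":
        keys = {
            "LR": ("lr_reg", "lr_solver", "lam_lr"),
            "SVM": ("svm_kernel", "box_constraint", "kernel_scale", "epsilon"),
            "GPR": ("gpr_basis", "gpr_kernel", "sigma"),
        }[family]
        kwargs = {k: decoded[k] for k in keys if k in decoded}
        return cls(
            family=family,
            standardize=decoded.get("standardize", "No") == "Yes",
            **kwargs,
        )


_GPR_KERNELS = {
    "Exponential": lambda d: Matern(length_scale=np.ones(d), nu=0.5,
                                    length_scale_bounds=(1e-3, 1e4)),
    "Squared Exponential": lambda d: RBF(length_scale=np.ones(d),
                                         length_scale_bounds=(1e-3, 1e4)),
    "Matern 3/2": lambda d: Matern(length_scale=np.ones(d), nu=1.5,
                                   length_scale_bounds=(1e-3, 1e4)),
    "Matern 5/2": lambda d: Matern(length_scale=np.ones(d), nu=2.5,
                                   length_scale_bounds=(1e-3, 1e4)),
    "Rational Quadratic": lambda d: RationalQuadratic(
        length_scale=1.0, alpha=1.0, length_scale_bounds=(1e-3, 1e4)),
}


def _gpr_basis_design(X: np.ndarray, basis: str) -> np.ndarray | None:
    if basis == "None":
        return None
    if basis == "Constant":
        return np.ones((X.shape[0], 1))
    if basis == "Linear":
        return np.column_stack([np.ones(X.shape[0]), X])
    if basis == "Pure Quadratic":
        return np.column_stack([np.ones(X.shape[0]), X, X**2])
    raise ValueError(f"unknown GPR basis {basis!r}")


class PeakPowerRegressor(RegressorMixin, BaseEstimator):
    """Sklearn-style estimator over the three model families.

    Parameters mirror :class:`ModelParams`; ``fit`` expects the FPC score
    matrix X (n_jumps, p) and peak power y (W/kg), and ``predict`` always
    returns outcome units regardless of the standardisation flag.
    """

    def __init__(self, family: str = "GPR", standardize: bool = False,
                 lr_reg: str = "Ridge", lr_solver: str = "Least Squares",
                 lam_lr: float = 1e-3, svm_kernel: str = "Gaussian",
                 box_constraint: float = 1.0, kernel_scale: float = 1.0,
                 epsilon: float = 0.1, gpr_basis: str = "Constant",
                 gpr_kernel: str = "Matern 5/2", sigma: float = 0.1,
                 random_state: int | None = 0):
        self.family = family
        self.standardize = standardize
        self.lr_reg = lr_reg
        self.lr_solver = lr_solver
        self.lam_lr = lam_lr
        self.svm_kernel = svm_kernel
        self.box_constraint = box_constraint
        self.kernel_scale = kernel_scale
        self.epsilon = epsilon
        self.gpr_basis = gpr_basis
        self.gpr_kernel = gpr_kernel
        self.sigma = sigma
        self.random_state = random_state

    @classmethod
    def from_params(cls, params: ModelParams,
                    random_state: int | None = 0) -> "PeakPowerRegressor":
        kwargs = {k: v for k, v in params.__dict__.items()}
        return cls(random_state=random_state, **kwargs)

    # -- family-specific inner estimators ---------------------------------
    def _make_linear(self):
        n = self._n_train
        if self.lr_solver == "Least Squares":
            if self.lr_reg == "Ridge":
                # per-observation penalty scale, matching the lasso solver
                return Ridge(alpha=self.lam_lr * n)
            return Lasso(alpha=self.lam_lr, max_iter=50_000)
        # epsilon-insensitive linear formulation; inputs are scaled
        # internally for solver stability and mapped back at prediction
        # (a solver detail, not the Z option)
        if self.lr_reg == "Ridge":
            svr = LinearSVR(
                C=1.0 / (self.lam_lr * self._n_train + 1e-12), epsilon=0.01,
                max_iter=50_000, random_state=self.random_state,
            )
            return Pipeline([("scale", StandardScaler()), ("svr", svr)])
        sgd = SGDRegressor(
            loss="epsilon_insensitive", epsilon=0.01, penalty="l1",
            alpha=self.lam_lr, max_iter=10_000, tol=1e-5,
            random_state=self.random_state,
        )
        return Pipeline([("scale", StandardScaler()), ("sgd", sgd)])

    def _make_svm(self):
        kernel = {"Gaussian": "rbf", "Linear": "linear", "Polynomial": "poly"}[
            self.svm_kernel
        ]
        return SVR(
            kernel=kernel,
            C=self.box_constraint,
            epsilon=self.epsilon,
            gamma=1.0 / self.kernel_scale**2,
            degree=3,
            max_iter=200_000,
        )

    def _make_gpr(self, d: int):
        kernel = ConstantKernel(1.0, (1e-4, 1e4)) * _GPR_KERNELS[self.gpr_kernel](d)
        return GaussianProcessRegressor(
            kernel=kernel,
            alpha=self.sigma**2,
            normalize_y=False,
            n_restarts_optimizer=0,
            random_state=self.random_state,
        )

    # ----------------------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        self._n_train = X.shape[0]
        self.n_features_in_ = X.shape[1]

        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            self.x_sd_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
            self.y_mean_ = float(y.mean())
            self.y_sd_ = float(y.std()) or 1.0
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.x_sd_ = np.ones(X.shape[1])
            self.y_mean_, self.y_sd_ = 0.0, 1.0
        Xs = (X - self.x_mean_) / self.x_sd_
        ys = (y - self.y_mean_) / self.y_sd_

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if self.family == "LR":
                self.estimator_ = self._make_linear().fit(Xs, ys)
            elif self.family == "SVM":
                self.estimator_ = self._make_svm().fit(Xs, ys)
            elif self.family == "GPR":
                H = _gpr_basis_design(Xs, self.gpr_basis)
                if H is None:
                    self._basis_coef = None
                    resid = ys
                else:
                    coef, *_ = np.linalg.lstsq(H, ys, rcond=None)
                    self._basis_coef = coef
                    resid = ys - H @ coef
                self.estimator_ = self._make_gpr(Xs.shape[1]).fit(Xs, resid)
            else:
                raise ValueError(f"unknown family {self.family!r}")
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_}"
            )
        Xs = (X - self.x_mean_) / self.x_sd_
        pred = self.estimator_.predict(Xs)
        if self.family == "GPR" and self._basis_coef is not None:
            H = _gpr_basis_design(Xs, self.gpr_basis)
            pred = pred + H @ self._basis_coef
        return pred * self.y_sd_ + self.y_mean_


def baseline_flight_time_model(
    flight_times: np.ndarray,
    masses: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[LinearRegression, float]:
    """Simple comparison baseline: ordinary least squares of peak power on
    flight time and body mass, with a K-fold cross-validated RMSE."""
    X = np.column_stack([np.asarray(flight_times, float), np.asarray(masses, float)])
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 jumps for the baseline model")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < 3:
        raise ValueError("degenerate (collinear) predictors")
    errs = []
    for train, test in KFold(n_folds, shuffle=True, random_state=seed).split(X):
        model = LinearRegression().fit(X[train], y[train])
        errs.append(np.mean((model.predict(X[test]) - y[test]) ** 2))
    cv_rmse = float(np.sqrt(np.mean(errs)))
    return LinearRegression().fit(X, y), cv_rmse
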