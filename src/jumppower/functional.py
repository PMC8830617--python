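"""B-spline functional representation and functional PCA.

Windowed accelerometer series are converted to smooth functions by
penalised least squares on a uniform-knot b-spline basis.  The basis size
is defined through a density rho (functions per second) so it is
independent of the window length, with a floor at the spline order; the
roughness penalty lambda acts on the 2nd or 3rd derivative, as encoded by
the basis code Phi = "<order>-<penalty order>".

FPCA is an eigen-decomposition of the sample covariance operator expressed
in the b-spline basis: with Gram matrix W (exact L2 inner products of
basis functions, Gauss-Legendre per knot interval) and coefficient
covariance V, the harmonics solve  W^(1/2) V W^(1/2) u = mu u,  giving
eigenfunctions orthonormal under the L2 inner product on the window.  No
rotation is applied, preserving the components' independence and the
natural amplitude ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, eigh
from sklearn.base import BaseEstimator, TransformerMixin

from .params import PHI_CODES


@dataclass(frozen=True)
class BasisSpec:
    """Spline order / penalty derivative (Phi code), basis density rho
    (functions/s), roughness penalty as log10(lambda), window duration."""

    phi: str
    rho: float
    log_lambda: float
    duration: float

    def __post_init__(self):
        if self.phi not in PHI_CODES:
            raise ValueError(f"invalid basis code {self.phi!r}; one of {PHI_CODES}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def order(self) -> int:
        return int(self.phi.split("-")[0])

    @property
    def penalty_order(self) -> int:
        return int(self.phi.split("-")[1])

    @property
    def n_basis(self) -> int:
        return max(self.order, int(round(self.rho * self.duration)))

    @property
    def lam(self) -> float:
        return 10.0**self.log_lambda


class BSplineBasis:
    """Uniform clamped b-spline basis on [0, duration]."""

    def __init__(self, order: int, n_basis: int, duration: float):
        if n_basis < order:
            raise ValueError("n_basis must be at least the spline order")
        self.order = order
        self.degree = order - 1
        self.n_basis = n_basis
        self.duration = duration
        n_interior = n_basis - order
        interior = np.linspace(0.0, duration, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.zeros(order), interior, np.full(order, duration)]
        )

    @classmethod
    def from_spec(cls, spec: BasisSpec) -> "BSplineBasis":
        return cls(spec.order, spec.n_basis, spec.duration)

    def design_matrix(self, t: np.ndarray, deriv: int = 0) -> np.ndarray:
        """Evaluate all basis functions (or a derivative) at ``t``;
        returns (len(t), n_basis)."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, self.duration)
        out = np.empty((t.size, self.n_basis))
        ident = np.eye(self.n_basis)
        for j in range(self.n_basis):
            sp = BSpline(self.knots, ident[j], self.degree, extrapolate=False)
            if deriv:
                sp = sp.derivative(deriv)
            vals = sp(t)
            # clamped-end evaluation: right limit at the final knot
            vals = np.nan_to_num(vals, nan=0.0)
            if t[-1] == self.duration:
                left = sp(self.duration - 1e-9 * self.duration)
                vals[t == self.duration] = np.nan_to_num(left, nan=0.0)
            out[:, j] = vals
        return out

    def _quad_grid(self, npts: int = 8) -> tuple[np.ndarray, np.ndarray]:
        xg, wg = leggauss(npts)
        breaks = np.unique(self.knots)
        pts, wts = [], []
        for a, b in zip(breaks[:-1], breaks[1:]):
            pts.append(0.5 * (b - a) * xg + 0.5 * (a + b))
            wts.append(0.5 * (b - a) * wg)
        return np.concatenate(pts), np.concatenate(wts)

    def penalty_matrix(self, deriv: int) -> np.ndarray:
        """Exact integral of products of the ``deriv``-th derivatives
        (deriv = 0 gives the Gram matrix W)."""
        cache = getattr(self, "_pen_cache", None)
        if cache is None:
            cache = self._pen_cache = {}
        if deriv not in cache:
            pts, wts = self._quad_grid()
            D = self.design_matrix(pts, deriv=deriv)
            cache[deriv] = (D * wts[:, None]).T @ D
        return cache[deriv]

    def gram_matrix(self) -> np.ndarray:
        return self.penalty_matrix(0)


#: memo of (basis, grid, design matrix, B'B) keyed by basis geometry —
#: the optimiser revisits the same window/basis combinations constantly
_BASIS_CACHE: dict = {}


class SingularFitError(np.linalg.LinAlgError):
    """Penalised least squares system is singular (basis too rich for the
    sample with a vanishing penalty)."""


class BSplineSmoother(TransformerMixin, BaseEstimator):
    """Penalised least-squares smoothing of sampled curves onto a b-spline
    basis.

    Parameters
    ----------
    phi : str
        Basis code "<order>-<penalty order>" from the valid set.
    rho : float
        Basis density, functions per second.
    log_lambda : float
        log10 of the roughness penalty on the Phi-specified derivative.
    fs : float
        Sampling rate of the input curves (Hz).

    ``fit`` expects X of shape (n_curves, n_samples); ``transform`` maps
    curves to basis coefficients of shape (n_curves, n_basis).
    """

    def __init__(self, phi: str = "4-2", rho: float = 10.0,
                 log_lambda: float = 0.0, fs: float = 250.0):
        self.phi = phi
        self.rho = rho
        self.log_lambda = log_lambda
        self.fs = fs

    def _spec(self, n_samples: int) -> BasisSpec:
        return BasisSpec(self.phi, self.rho, self.log_lambda, n_samples / self.fs)

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        spec = self._spec(X.shape[1])
        self.spec_ = spec
        key = (spec.order, spec.n_basis, X.shape[1], self.fs)
        cached = _BASIS_CACHE.get(key)
        if cached is None:
            basis = BSplineBasis(spec.order, spec.n_basis, X.shape[1] / self.fs)
            t_grid = (np.arange(X.shape[1]) + 0.5) / self.fs
            B = basis.design_matrix(t_grid)
            if len(_BASIS_CACHE) > 64:
                _BASIS_CACHE.clear()
            _BASIS_CACHE[key] = cached = (basis, t_grid, B, B.T @ B)
        self.basis_, self.t_grid_, B, BtB = cached
        P = self.basis_.penalty_matrix(spec.penalty_order)
        A = BtB + spec.lam * P
        try:
            self._cho = cho_factor(A)
        except np.linalg.LinAlgError as exc:
            raise SingularFitError(str(exc)) from exc
        self._B = B
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._B.shape[0]:
            raise ValueError("curve length does not match the fitted grid")
        return cho_solve(self._cho, self._B.T @ X.T).T

    def evaluate(self, coefs: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Evaluate smoothed curves (rows of coefficients) at times t."""
        return np.atleast_2d(coefs) @ self.basis_.design_matrix(np.asarray(t)).T


class FPCA(TransformerMixin, BaseEstimator):
    """Functional principal component analysis in a b-spline basis.

    Fitted on basis-coefficient rows from a :class:`BSplineSmoother`;
    ``transform`` returns the FPC scores (L2 inner products of the centred
    curves with each retained eigenfunction).  Training-set scores are
    centred by construction and their per-component variance equals the
    corresponding eigenvalue.
    """

    def __init__(self, n_components: int = 3, basis: BSplineBasis | None = None):
        self.n_components = n_components
        self.basis = basis

    def fit(self, X, y=None):
        C = np.atleast_2d(np.asarray(X, dtype=float))
        n_curves, n_basis = C.shape
        if self.basis is None or self.basis.n_basis != n_basis:
            raise ValueError("FPCA requires the basis the coefficients live in")
        if self.n_components > n_basis:
            raise ValueError(
                f"n_components={self.n_components} exceeds n_basis={n_basis}"
            )
        if self.n_components >= n_curves:
            raise ValueError(
                f"n_components={self.n_components} requires more than "
                f"{n_curves} training curves"
            )
        W = self.basis.gram_matrix()
        # symmetric square root of the Gram matrix
        w_vals, w_vecs = eigh(W)
        w_vals = np.clip(w_vals, 1e-12, None)
        W_half = (w_vecs * np.sqrt(w_vals)) @ w_vecs.T
        W_half_inv = (w_vecs / np.sqrt(w_vals)) @ w_vecs.T
        self.mean_ = C.mean(axis=0)
        Cc = C - self.mean_
        V = (Cc.T @ Cc) / (n_curves - 1)
        M = W_half @ V @ W_half
        mu, U = eigh(M)
        order = np.argsort(mu)[::-1]
        mu = np.clip(mu[order], 0.0, None)
        U = U[:, order]
        k = self.n_components
        self.eigenvalues_ = mu[:k]
        self.components_ = (W_half_inv @ U[:, :k]).T  # rows: eigenfunction coefs
        self._W = W
        return self

    def transform(self, X) -> np.ndarray:
        C = np.atleast_2d(np.asarray(X, dtype=float))
        if C.shape[1] != self.mean_.size:
            raise ValueError("coefficient dimension does not match the fitted basis")
        return (C - self.mean_) @ self._W @ self.components_.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Basis coefficients of the curves rebuilt from scores."""
        return self.mean_ + np.atleast_2d(scores) @ self.components_


def fit_fpca_scores(
    train_curves: np.ndarray,
    other_curves: np.ndarray | None,
    smoother: BSplineSmoother,
    n_components: int,
) -> tuple[np.ndarray, np.ndarray | None, FPCA]:
    """Smooth + FPCA fitted on the training curves alone; scores for the
    training set and (optionally) a second set using the training-set mean
    and eigenfunctions — the leakage-safe path used inside the objective."""
    smoother.fit(train_curves)
    C_train = smoother.transform(train_curves)
    fpca = FPCA(n_components=n_components, basis=smoother.basis_).fit(C_train)
    s_train = fpca.transform(C_train)
    s_other = None
    if other_curves is not None:
        s_other = fpca.transform(smoother.transform(other_curves))
    return s_train, s_other, fpca
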