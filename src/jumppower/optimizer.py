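"""Surrogate-assisted optimisation of the noisy AM objective.

A random search draws candidates uniformly over the wide parameter ranges
and screens them against a Gaussian-process surrogate fitted to all
(parameters, loss) observations so far: candidates whose predicted loss
exceeds a progressively tightening ceiling L_max are accepted only with
probability exp(-(L - L_max)^2 / (2 delta^2)).  The ceiling is
L_max = L0 + alpha_j * SD(L) with a ramp alpha_j descending linearly from
0.5 to 0 over the first half of the surrogate refits and zero thereafter,
so the search surveys the space before focusing on promising regions.

The surrogate (anisotropic Matern 5/2 kernel, constant mean offset, raw
predictors) is refitted every ``refit_every`` observations, and particle
swarm optimisation is run on each refitted surrogate (categorical and
integer coordinates rounded inside the swarm's objective).  The final
*ensemble* parameter vector is assembled by maximum likelihood over the
PSO optima from the unconstrained-ramp (alpha = 0) phase: the modal
category for categoricals and the kernel-density peak for numerics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .params import ParamSpace


def alpha_schedule(j: int, n_refits: int) -> float:
    """Constraint ramp: linear descent 0.5 -> 0 across refits 1..ceil(n/2),
    zero for the second half."""
    if not 1 <= j <= n_refits:
        raise ValueError(f"refit index {j} outside 1..{n_refits}")
    half = int(np.ceil(n_refits / 2))
    if j >= half or half == 1:
        return 0.0
    return 0.5 * (half - j) / (half - 1)


def acceptance_probability(l_pred: float, l_max: float, delta: float) -> float:
    """Probability of accepting a candidate with surrogate-predicted loss
    ``l_pred`` under ceiling ``l_max`` and acceptance width ``delta``."""
    if l_pred <= l_max:
        return 1.0
    if delta <= 0:
        return 0.0
    return float(np.exp(-((l_pred - l_max) ** 2) / (2.0 * delta**2)))


class SurrogateModel:
    """GP regression of loss on the indexed parameter vector: anisotropic
    Matern 5/2 plus fitted white noise, constant mean offset, predictors
    unstandardised."""

    def __init__(self, space: ParamSpace, seed: int = 0):
        self.space = space
        self.seed = seed
        self.gp_: GaussianProcessRegressor | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SurrogateModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        d = X.shape[1]
        scale = np.maximum(X.max(axis=0) - X.min(axis=0), 1e-3)
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * Matern(length_scale=scale, length_scale_bounds=(1e-3, 1e4), nu=2.5)
            + WhiteKernel(0.1, (1e-8, 1e2))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp_ = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, n_restarts_optimizer=2,
                random_state=self.seed, alpha=1e-10,
            ).fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.gp_.predict(X)


@dataclass
class SearchState:
    """Constraint-schedule state after the j-th surrogate refit."""

    j: int
    n_refits: int
    l0: float
    sd_loss: float

    @property
    def alpha(self) -> float:
        return alpha_schedule(self.j, self.n_refits)

    @property
    def l_max(self) -> float:
        return self.l0 + self.alpha * self.sd_loss

    @property
    def delta(self) -> float:
        return 0.5 * self.sd_loss


@dataclass
class RefitRecord:
    j: int
    alpha: float
    l0: float
    sd_loss: float
    optimum: np.ndarray
    optimum_pred: float


@dataclass
class OptimizationTrace:
    """Full record of one optimisation: observations, refit schedule and
    the PSO optimum series."""

    X: list = field(default_factory=list)
    losses: list = field(default_factory=list)
    refits: list[RefitRecord] = field(default_factory=list)
    n_screened: int = 0
    ensemble: np.ndarray | None = None

    def eligible_optima(self) -> list[np.ndarray]:
        """PSO optima from the alpha = 0 (second-half) phase."""
        return [r.optimum for r in self.refits if r.alpha == 0.0]

    def to_json(self, path) -> None:
        payload = {
            "observations": [list(map(float, x)) for x in self.X],
            "losses": list(map(float, self.losses)),
            "n_screened": self.n_screened,
            "refits": [
                {
                    "j": r.j, "alpha": r.alpha, "l0": r.l0, "sd_loss": r.sd_loss,
                    "optimum": list(map(float, r.optimum)),
                    "optimum_pred": r.optimum_pred,
                }
                for r in self.refits
            ],
            "ensemble": None if self.ensemble is None
            else list(map(float, self.ensemble)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def pso_minimize(
    predict_fn,
    space: ParamSpace,
    rng: np.random.Generator,
    n_particles: int = 100,
    tol: float = 1e-3,
    max_iter: int = 200,
    stall_iters: int = 20,
) -> tuple[np.ndarray, float]:
    """Global-best particle swarm on the rounded-parameter surrogate.

    Standard constriction dynamics (inertia 0.729, cognitive/social 1.494);
    particles are confined to the padded optimisation bounds and the
    returned optimum has integer/categorical coordinates rounded.
    Terminates when the best objective improves by less than ``tol`` over
    ``stall_iters`` consecutive iterations.
    """
    lo, hi = space.bounds_arrays()
    d = lo.size
    pos = rng.uniform(lo, hi, size=(n_particles, d))
    vel = rng.uniform(-(hi - lo), hi - lo, size=(n_particles, d)) * 0.1

    def f(P):
        vals = predict_fn(space.round_vector(P))
        if not np.all(np.isfinite(vals)):
            raise FloatingPointError("non-finite surrogate prediction")
        return vals

    pbest = pos.copy()
    pbest_val = f(pos)
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    w, c1, c2 = 0.729, 1.494, 1.494
    stall, last_best = 0, gbest_val
    for _ in range(max_iter):
        r1 = rng.random((n_particles, d))
        r2 = rng.random((n_particles, d))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        vals = f(pos)
        better = vals < pbest_val
        pbest[better] = pos[better]
        pbest_val[better] = vals[better]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        if last_best - gbest_val < tol:
            stall += 1
            if stall >= stall_iters:
                break
        else:
            stall = 0
        last_best = gbest_val
    return space.round_vector(gbest), gbest_val


def constrained_random_search(
    objective,
    space: ParamSpace,
    n_obs: int = 400,
    refit_every: int = 20,
    seed: int = 0,
    n_particles: int = 100,
    pso_tol: float = 1e-3,
    max_reject: int = 500,
    surrogate_cls=SurrogateModel,
) -> tuple[OptimizationTrace, SurrogateModel | None]:
    """Run the constrained random search with periodic surrogate refits
    and PSO.  ``objective`` maps a (rounded) internal parameter vector to a
    scalar loss.  Returns the trace and the final surrogate."""
    if n_obs % refit_every:
        raise ValueError("n_obs must be a multiple of refit_every")
    rng = np.random.default_rng(seed)
    n_refits = n_obs // refit_every
    trace = OptimizationTrace()
    surrogate: SurrogateModel | None = None
    state: SearchState | None = None

    consecutive_failures = 0
    for i in range(1, n_obs + 1):
        if surrogate is None:
            cand = space.round_vector(space.sample_wide(rng))
        else:
            cand = None
            best_cand, best_p = None, -1.0
            for _ in range(max_reject):
                c = space.round_vector(space.sample_wide(rng))
                l_pred = float(surrogate.predict(c[None, :])[0])
                p = acceptance_probability(l_pred, state.l_max, state.delta)
                trace.n_screened += 1
                if rng.random() < p:
                    cand = c
                    break
                if p > best_p:
                    best_cand, best_p = c, p
            if cand is None:
                cand = best_cand  # force-accept the most probable reject
        loss = float(objective(cand))
        if not np.isfinite(loss):
            consecutive_failures += 1
            if consecutive_failures > 50:
                raise RuntimeError("objective failed repeatedly; aborting search")
            continue
        consecutive_failures = 0
        trace.X.append(cand)
        trace.losses.append(loss)

        if i % refit_every == 0:
            j = i // refit_every
            X = np.array(trace.X)
            y = np.array(trace.losses)
            surrogate = surrogate_cls(space, seed=seed).fit(X, y)
            preds = surrogate.predict(X)
            state = SearchState(
                j=j, n_refits=n_refits,
                l0=float(preds.min()), sd_loss=float(preds.std()),
            )
            optimum, opt_pred = pso_minimize(
                surrogate.predict, space, rng,
                n_particles=n_particles, tol=pso_tol,
            )
            trace.refits.append(
                RefitRecord(j, state.alpha, state.l0, state.sd_loss,
                            optimum, float(opt_pred))
            )
    return trace, surrogate


def _kde_peak(values: np.ndarray, lo: float, hi: float) -> float:
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2 or values.std() == 0:
        return float(values[0])
    try:
        kde = gaussian_kde(values)  # Silverman bandwidth
    except np.linalg.LinAlgError:
        return float(np.median(values))
    grid = np.linspace(min(lo, values.min()), max(hi, values.max()), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def select_ensemble(
    optima: list[np.ndarray], space: ParamSpace, validity_fn=None
) -> np.ndarray:
    """Maximum-likelihood ensemble parameter vector from a series of PSO
    optima: modal category for categoricals (ties to the lowest index),
    kernel-density peak for numerics (integers rounded afterwards).

    ``validity_fn`` may exclude optima that are not valid parameter
    combinations.
    """
    if validity_fn is not None:
        optima = [x for x in optima if validity_fn(x)]
    if len(optima) < 1:
        raise ValueError("no eligible optima for ensemble selection")
    A = np.array(optima, dtype=float)
    out = np.empty(space.ndim)
    for k, p in enumerate(space.params):
        col = A[:, k]
        if p.ptype == "C":
            idx, counts = np.unique(np.round(col).astype(int), return_counts=True)
            out[k] = idx[np.argmax(counts)]  # np.unique sorts: ties -> lowest
        elif p.ptype == "I":
            out[k] = np.round(_kde_peak(col, *p.bounds))
        else:
            out[k] = _kde_peak(col, *p.bounds)
    return out
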