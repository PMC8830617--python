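"""Nested cross validation, the factorial condition grid, holdout
evaluation and the iterative refinement loop.

The outer loop is a repeated participant-level K-fold partition; for each
outer fold the surrogate-assisted search optimises the full parameter
vector on the outer training set (inner 2-fold CV objective), an ensemble
parameter vector is assembled from the PSO optima, trained on the outer
training set and evaluated on the outer validation set.  The NCV estimate
is the mean +/- SD of the outer-fold RMSEs.  A final ensemble over all
folds' optima is trained on the whole training/validation set and may be
evaluated once on the held-out participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import rmse
from .objective import AccelerometerObjective, validate_params
from .optimizer import constrained_random_search, select_ensemble
from .pipeline import (
    AccelPowerPipeline,
    InvalidParamsError,
    LeakageError,
    TrialFeatures,
)
from .params import ParamSpace


@dataclass(frozen=True)
class Fold:
    repetition: int
    fold: int
    train_ids: tuple
    val_ids: tuple


@dataclass
class FoldPlan:
    """Repeated participant-level K-fold partition."""

    folds: list[Fold]
    n_folds: int
    n_reps: int

    def check(self) -> None:
        """Assert the partition invariants; raises LeakageError."""
        for rep in range(self.n_reps):
            rep_folds = [f for f in self.folds if f.repetition == rep]
            seen: list = []
            for f in rep_folds:
                if set(f.train_ids) & set(f.val_ids):
                    raise LeakageError("participant in both train and validation")
                seen.extend(f.val_ids)
            if len(seen) != len(set(seen)):
                raise LeakageError("participant in more than one validation fold")


def make_fold_plan(
    participant_ids, n_folds: int = 10, n_reps: int = 2, seed: int = 0
) -> FoldPlan:
    """Deterministic repeated participant-level K-fold plan."""
    ids = np.asarray(sorted(participant_ids))
    if ids.size < n_folds:
        raise ValueError(f"{ids.size} participants cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    folds = []
    for rep in range(n_reps):
        perm = rng.permutation(ids)
        groups = np.array_split(perm, n_folds)
        for k, val in enumerate(groups):
            train = np.setdiff1d(perm, val)
            folds.append(Fold(rep, k, tuple(sorted(train)), tuple(sorted(val))))
    plan = FoldPlan(folds, n_folds, n_reps)
    plan.check()
    return plan


@dataclass
class FoldResult:
    repetition: int
    fold: int
    ensemble: np.ndarray          # internal parameter vector
    val_rmse: float
    optima: list = field(default_factory=list)


@dataclass
class ConditionResult:
    """All outer-fold results for one experimental condition."""

    signal: str
    family: str
    fold_results: list[FoldResult]
    final_ensemble: np.ndarray
    final_pipeline: AccelPowerPipeline | None = None

    @property
    def fold_rmses(self) -> np.ndarray:
        return np.array([f.val_rmse for f in self.fold_results])

    @property
    def ncv_estimate(self) -> tuple[float, float]:
        errs = self.fold_rmses
        return float(errs.mean()), float(errs.std(ddof=1))


@dataclass
class OptimizerSettings:
    """Search effort knobs (full-scale defaults match the study design)."""

    n_obs: int = 400
    refit_every: int = 20
    n_particles: int = 100
    pso_tol: float = 1e-3


def _fit_ensemble(
    features: TrialFeatures,
    mask: np.ndarray,
    ensemble: np.ndarray,
    space: ParamSpace,
    family: str,
    signal: str,
    fallbacks: list[tuple[float, np.ndarray]] | None = None,
) -> tuple[np.ndarray, AccelPowerPipeline]:
    """Fit the ensemble parameter vector; if the blended vector is not a
    fittable combination (e.g. a singular smoothing system), fall back to
    the observed vectors in order of increasing loss."""
    candidates = [ensemble]
    if fallbacks:
        candidates += [x for _, x in sorted(fallbacks, key=lambda t: t[0])]
    last_exc: Exception | None = None
    for cand in candidates:
        try:
            pipe = AccelPowerPipeline(space.decode(cand), family, signal).fit(
                features, mask
            )
            return cand, pipe
        except InvalidParamsError as exc:
            last_exc = exc
    raise InvalidParamsError(
        f"no fittable parameter vector among ensemble and fallbacks: {last_exc}"
    )


def _check_ensemble(
    ensemble: np.ndarray,
    objective: AccelerometerObjective,
    losses: list[float],
    fallbacks: list[tuple[float, np.ndarray]],
    slack: float = 0.2,
) -> np.ndarray:
    """Acceptance check on the assembled ensemble: density blending of few
    optima can occasionally land in a high-loss region none of the optima
    endorsed.  The ensemble is evaluated once on the (outer-train)
    objective; if it is clearly worse than the best observed vector it is
    replaced by that vector.  Uses training data only — no leakage."""
    best_loss = float(np.min(losses))
    ens_loss = objective(ensemble)
    if ens_loss <= 2.0 * best_loss + slack:
        return ensemble
    return min(fallbacks, key=lambda t: t[0])[1]


def run_ncv(
    features: TrialFeatures,
    space: ParamSpace,
    family: str,
    signal: str = "resultant",
    plan: FoldPlan | None = None,
    settings: OptimizerSettings | None = None,
    n_folds: int = 10,
    n_reps: int = 2,
    seed: int = 0,
) -> ConditionResult:
    """Nested cross validation for one condition (family x signal on the
    given trial set); returns fold results, the NCV estimate and the final
    ensemble pipeline trained on the full training/validation set."""
    settings = settings or OptimizerSettings()
    if plan is None:
        plan = make_fold_plan(
            np.unique(features.participant_ids), n_folds, n_reps, seed
        )
    plan.check()
    fold_results = []
    all_optima: list[np.ndarray] = []
    n_train_half = None
    for f_i, fold in enumerate(plan.folds):
        train_mask = features.subset_mask(set(fold.train_ids))
        val_mask = features.subset_mask(set(fold.val_ids))
        if np.any(train_mask & val_mask):
            raise LeakageError("outer train/validation trial overlap")
        objective = AccelerometerObjective(
            features, space, family, signal,
            train_mask=train_mask, seed=seed * 10_000 + f_i,
        )
        trace, _ = constrained_random_search(
            objective, space,
            n_obs=settings.n_obs, refit_every=settings.refit_every,
            seed=seed * 10_000 + f_i,
            n_particles=settings.n_particles, pso_tol=settings.pso_tol,
        )
        n_train_half = int(train_mask.sum()) // 2
        valid = lambda x: validate_params(space.decode(x), n_train_half)  # noqa: E731
        optima = trace.eligible_optima()
        ensemble = select_ensemble(optima, space, validity_fn=valid)
        fallbacks = list(zip(trace.losses, trace.X))
        ensemble = _check_ensemble(ensemble, objective, trace.losses, fallbacks)
        ensemble, pipe = _fit_ensemble(
            features, train_mask, ensemble, space, family, signal, fallbacks
        )
        err = rmse(pipe.predict(features, val_mask), features.y[val_mask])
        fold_results.append(
            FoldResult(fold.repetition, fold.fold, ensemble, err, optima)
        )
        all_optima.extend(optima)
        all_fallbacks = fallbacks if f_i == 0 else all_fallbacks + fallbacks
    final = select_ensemble(
        all_optima, space,
        validity_fn=lambda x: validate_params(space.decode(x), n_train_half),
    )
    full_mask = np.ones(features.n_trials, bool)
    full_objective = AccelerometerObjective(
        features, space, family, signal, seed=seed * 10_000 + 999
    )
    final = _check_ensemble(
        final, full_objective, [t[0] for t in all_fallbacks], all_fallbacks
    )
    final, final_pipe = _fit_ensemble(
        features, full_mask, final, space, family, signal, all_fallbacks
    )
    return ConditionResult(signal, family, fold_results, final, final_pipe)


def evaluate_holdout(
    final_pipeline: AccelPowerPipeline,
    train_features: TrialFeatures,
    holdout_features: TrialFeatures,
) -> float:
    """Single independent RMSE on never-touched participants.  Any
    participant overlap with the training set is a hard failure."""
    overlap = set(train_features.participant_ids) & set(
        holdout_features.participant_ids
    )
    if overlap:
        raise LeakageError(f"holdout participants seen in training: {sorted(overlap)}")
    pred = final_pipeline.predict(holdout_features)
    return rmse(pred, holdout_features.y)


def refine(
    optima: list[np.ndarray],
    space: ParamSpace,
    modal_threshold: float = 0.5,
    kde_mass_threshold: float = 0.5,
    width_frac: float = 0.05,
) -> ParamSpace:
    """Freeze parameters whose optima distribution is sufficiently peaked.

    Categoricals are frozen at the mode when its share of the optima is at
    least ``modal_threshold``; numerics are frozen at the density peak when
    at least ``kde_mass_threshold`` of the optima fall within
    ``width_frac`` of the optimisation range around the peak.  Returns the
    narrowed space for the next optimisation round.
    """
    if not optima:
        raise ValueError("refinement needs at least one completed round")
    A = np.array(optima, dtype=float)
    ensemble = select_ensemble(optima, space)
    frozen: dict[str, float] = {}
    for k, p in enumerate(space.params):
        col = A[:, k]
        if p.ptype == "C":
            share = np.mean(np.round(col) == ensemble[k])
            if share >= modal_threshold:
                frozen[p.name] = ensemble[k]
        else:
            lo, hi = p.bounds
            width = width_frac * (hi - lo)
            mass = np.mean(np.abs(col - ensemble[k]) <= width)
            if mass >= kde_mass_threshold:
                frozen[p.name] = ensemble[k]
    if not frozen:
        return space
    if len(frozen) == space.ndim:
        frozen.pop(space.params[-1].name)  # keep at least one free parameter
    return space.freeze(frozen)
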