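"""The accelerometer-model (AM) objective function.

One full parameter vector maps to a loss: the mean validation RMSE of an
inner 2-fold, participant-level cross validation on the outer training
set.  FPCs are defined on the inner training half alone and used to score
both halves.  Invalid parameter combinations (too few basis functions for
the requested FPCs, rank-deficient score matrix, window outside the padded
extent) return a fixed high loss, and valid losses are capped at the same
value so occasional extreme errors cannot destabilise the optimiser.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .functional import BasisSpec
from .models import rmse
from .pipeline import AccelPowerPipeline, InvalidParamsError, LeakageError, TrialFeatures
from .params import ParamSpace

LOSS_CAP = 10.0  # W/kg


@dataclass(frozen=True)
class AMResult:
    loss: float           # capped, in [0, LOSS_CAP]
    valid: bool
    raw_rmse: float | None  # uncapped mean fold RMSE when valid
    seconds: float


def validate_params(decoded: dict, n_train_curves: int) -> bool:
    """Cheap validity verdict for a decoded parameter vector: enough basis
    functions for the requested FPCs and a feasible window.  (Rank of the
    realised score matrix is checked during evaluation.)"""
    duration = decoded["t_pre"] + decoded["t_post"]
    if duration <= 0:
        return False
    try:
        spec = BasisSpec(decoded["phi"], decoded["rho"], np.log10(decoded["lam"]),
                         duration)
    except ValueError:
        return False
    return decoded["n_fpc"] <= spec.n_basis and decoded["n_fpc"] < n_train_curves


def split_participants_two_fold(
    participant_ids: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random participant-level halves (floor/ceil split); returns boolean
    trial masks.  No participant's jumps appear in both halves."""
    unique = np.unique(participant_ids)
    if unique.size < 4:
        raise ValueError("need at least 4 participants for the inner 2-fold split")
    perm = rng.permutation(unique)
    half = unique.size // 2
    set_a = set(perm[:half])
    mask_a = np.isin(participant_ids, list(set_a))
    return mask_a, ~mask_a


class AccelerometerObjective:
    """Callable AM objective over a fixed outer-training trial set.

    Parameters
    ----------
    features : TrialFeatures
        Preprocessed, take-off-aligned trials.
    train_mask : bool array, optional
        Restrict to the outer training subset.
    space : ParamSpace
        Decodes internal parameter vectors.
    family, signal : condition under evaluation.
    seed : base seed; by default the inner split is re-drawn on every call
        (the stochastic objective the surrogate model expects).  With
        ``reseed_per_call=False`` a single fixed split is reused, making
        the objective deterministic.
    """

    def __init__(self, features: TrialFeatures, space: ParamSpace, family: str,
                 signal: str = "resultant", train_mask: np.ndarray | None = None,
                 seed: int = 0, reseed_per_call: bool = True,
                 inner_repeats: int = 1):
        self.features = features
        self.space = space
        self.family = family
        self.signal = signal
        self.train_mask = (
            np.ones(features.n_trials, bool) if train_mask is None else train_mask
        )
        self.rng = np.random.default_rng(seed)
        self.reseed_per_call = reseed_per_call
        self.inner_repeats = inner_repeats
        if not self.reseed_per_call:
            self._fixed_split = split_participants_two_fold(
                features.participant_ids[self.train_mask], self.rng
            )
        self.n_evaluations = 0
        self.log: list[dict] = []

    def __call__(self, x: np.ndarray) -> float:
        return self.evaluate(x).loss

    def evaluate(self, x: np.ndarray) -> AMResult:
        t0 = time.perf_counter()
        decoded = self.space.decode(np.asarray(x, dtype=float))
        self.n_evaluations += 1
        train_pids = self.features.participant_ids[self.train_mask]
        if not validate_params(decoded, int(self.train_mask.sum()) // 2):
            return self._finish(None, t0, decoded)

        fold_errors = []
        try:
            for _ in range(self.inner_repeats):
                if self.reseed_per_call:
                    mask_a, mask_b = split_participants_two_fold(train_pids, self.rng)
                else:
                    mask_a, mask_b = self._fixed_split
                idx = np.nonzero(self.train_mask)[0]
                for fit_half, val_half in ((mask_a, mask_b), (mask_b, mask_a)):
                    fit_pids = set(train_pids[fit_half])
                    val_pids = set(train_pids[val_half])
                    if fit_pids & val_pids:
                        raise LeakageError(
                            "participants shared between inner halves"
                        )
                    fit_mask = np.zeros(self.features.n_trials, bool)
                    fit_mask[idx[fit_half]] = True
                    val_mask = np.zeros(self.features.n_trials, bool)
                    val_mask[idx[val_half]] = True
                    pipe = AccelPowerPipeline(
                        decoded, self.family, self.signal,
                        random_state=int(self.rng.integers(2**31 - 1))
                        if self.reseed_per_call else 0,
                    ).fit(self.features, fit_mask)
                    pred = pipe.predict(self.features, val_mask)
                    fold_errors.append(rmse(pred, self.features.y[val_mask]))
        except InvalidParamsError:
            return self._finish(None, t0, decoded)
        raw = float(np.mean(fold_errors))
        return self._finish(raw, t0, decoded)

    def _finish(self, raw: float | None, t0: float, decoded: dict) -> AMResult:
        seconds = time.perf_counter() - t0
        if raw is None:
            result = AMResult(LOSS_CAP, False, None, seconds)
        else:
            result = AMResult(min(raw, LOSS_CAP), True, raw, seconds)
        self.log.append(
            {"loss": result.loss, "valid": result.valid, "seconds": seconds}
        )
        return result
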