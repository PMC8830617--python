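"""The end-to-end accelerometer-to-peak-power pipeline for one parameter
vector: take-off-aligned padding, windowing, b-spline smoothing, FPCA and
model fitting.

Trials are preprocessed once into take-off-aligned arrays (a fixed margin
either side of take-off, padded with the trial's quiet-standing lead-in
mean) so that evaluating a candidate parameter vector reduces to slicing a
window, smoothing and fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import signals
from .functional import BSplineSmoother, FPCA, SingularFitError
from .models import PeakPowerRegressor
from .signals import FS_ACCEL
from .synthetic import Trial

SIGNALS = ("resultant", "triaxial")

#: margin either side of take-off in the aligned arrays, s (covers the
#: full 3.0 s range of the window parameters)
ALIGN_MARGIN_S = 3.0


class InvalidParamsError(ValueError):
    """Parameter combination cannot produce a valid model (insufficient
    basis functions for the requested FPCs, rank-deficient score matrix,
    window outside the padded extent, ...)."""


class LeakageError(AssertionError):
    """A participant crossed a train/validation/holdout boundary."""


@dataclass
class TrialFeatures:
    """Take-off-aligned accelerometer arrays plus targets for a trial set."""

    trial_ids: np.ndarray       # (n,)
    participant_ids: np.ndarray  # (n,)
    y: np.ndarray               # (n,) peak power targets, W/kg
    resultant: np.ndarray       # (n, L) aligned resultant, g
    triaxial: np.ndarray        # (n, 3, L) aligned per-axis, g
    flight_times: np.ndarray    # (n,) s, from the criterion VGRF
    body_masses: np.ndarray     # (n,) kg
    n_excluded: int = 0

    @property
    def n_trials(self) -> int:
        return self.y.size

    @property
    def takeoff_index(self) -> int:
        return self.resultant.shape[1] // 2

    def subset_mask(self, participant_set: set) -> np.ndarray:
        return np.isin(self.participant_ids, list(participant_set))


def _align_trial(accel: np.ndarray, takeoff_time: float, margin: int) -> np.ndarray:
    """Pad a (channels, n) series with its lead-in mean and slice the
    window of ``2 * margin`` samples centred on take-off."""
    accel = np.atleast_2d(accel)
    i_t = int(round(FS_ACCEL * takeoff_time))
    means = signals.leadin_mean(accel)
    pad_left = max(0, margin - i_t)
    pad_right = max(0, i_t + margin - accel.shape[1])
    padded = np.stack(
        [np.pad(ch, (pad_left, pad_right), constant_values=m)
         for ch, m in zip(accel, means)]
    )
    start = i_t + pad_left - margin
    return padded[:, start : start + 2 * margin]


def build_features(
    trials: list[Trial],
    targets: dict[str, float] | None = None,
    margin_s: float = ALIGN_MARGIN_S,
) -> TrialFeatures:
    """Detect take-off from each trial's synchronised VGRF, align and pad
    the accelerometer arrays, and attach the regression target (supplied,
    or the trial's linear-link / criterion value).

    Trials whose events cannot be detected are excluded with a count.
    """
    margin = int(round(margin_s * FS_ACCEL))
    ids, pids, ys, res, tri, fts, masses = [], [], [], [], [], [], []
    n_excluded = 0
    for tr in trials:
        try:
            takeoff, _, flight = signals.detect_takeoff_landing(tr.vgrf)
        except signals.EventDetectionError:
            n_excluded += 1
            continue
        takeoff_time = takeoff / signals.FS_FORCE
        aligned = _align_trial(tr.accel, takeoff_time, margin)
        if targets is not None:
            y = targets[tr.trial_id]
        elif tr.link_target is not None:
            y = tr.link_target
        else:
            y = signals.compute_criterion_peak_power(
                tr.vgrf_clean if tr.vgrf_clean is not None else tr.vgrf,
                tr.body_mass,
            )
        ids.append(tr.trial_id)
        pids.append(tr.participant_id)
        ys.append(y)
        tri.append(aligned)
        res.append(signals.resultant(aligned))
        fts.append(flight)
        masses.append(tr.body_mass)
    if not ids:
        raise ValueError("no usable trials")
    return TrialFeatures(
        trial_ids=np.array(ids),
        participant_ids=np.array(pids),
        y=np.array(ys),
        resultant=np.stack(res),
        triaxial=np.stack(tri),
        flight_times=np.array(fts),
        body_masses=np.array(masses),
        n_excluded=n_excluded,
    )


def window_slice(features: TrialFeatures, t_pre: float, t_post: float) -> slice:
    """Half-open sample window around take-off in the aligned arrays."""
    i_t = features.takeoff_index
    start = i_t - int(round(FS_ACCEL * t_pre))
    stop = i_t + int(round(FS_ACCEL * t_post))
    if stop - start <= 0:
        raise InvalidParamsError("window length must be positive")
    if start < 0 or stop > features.resultant.shape[1]:
        raise InvalidParamsError("window exceeds the padded extent")
    return slice(start, stop)


class AccelPowerPipeline:
    """Windowing + smoothing + FPCA + regression for one decoded parameter
    vector.

    Parameters are the decoded pipeline values (t_pre/t_post in seconds,
    rho, phi, lambda linear-scale, n_fpc, standardisation flag and the
    family hyperparameters).  ``fit`` learns the FPC basis and the model
    on the given trials; ``predict`` scores new trials with the training
    mean and eigenfunctions (no leakage of validation statistics).
    """

    def __init__(self, decoded: dict, family: str, signal: str = "resultant",
                 random_state: int | None = 0):
        if signal not in SIGNALS:
            raise ValueError(f"unknown signal representation {signal!r}")
        self.decoded = dict(decoded)
        self.family = family
        self.signal = signal
        self.random_state = random_state

    def _windowed(self, features: TrialFeatures, mask: np.ndarray) -> list[np.ndarray]:
        sl = window_slice(features, self.decoded["t_pre"], self.decoded["t_post"])
        if self.signal == "resultant":
            return [features.resultant[mask][:, sl]]
        return [features.triaxial[mask][:, ax, sl] for ax in range(3)]

    def _check_validity(self, n_curves: int):
        d = self.decoded
        duration = d["t_pre"] + d["t_post"]
        if duration <= 0:
            raise InvalidParamsError("non-positive window")
        from .functional import BasisSpec

        spec = BasisSpec(d["phi"], d["rho"], np.log10(d["lam"]), duration)
        if d["n_fpc"] > spec.n_basis:
            raise InvalidParamsError(
                f"{d['n_fpc']} FPCs requested but only {spec.n_basis} basis functions"
            )
        if d["n_fpc"] >= n_curves:
            raise InvalidParamsError("more FPCs than training curves")

    def fit(self, features: TrialFeatures, mask: np.ndarray | None = None):
        mask = np.ones(features.n_trials, bool) if mask is None else mask
        self._check_validity(int(mask.sum()))
        d = self.decoded
        self.smoothers_, self.fpcas_, blocks = [], [], []
        try:
            for curves in self._windowed(features, mask):
                sm = BSplineSmoother(
                    phi=d["phi"], rho=d["rho"], log_lambda=np.log10(d["lam"]),
                    fs=FS_ACCEL,
                ).fit(curves)
                C = sm.transform(curves)
                fp = FPCA(n_components=d["n_fpc"], basis=sm.basis_).fit(C)
                self.smoothers_.append(sm)
                self.fpcas_.append(fp)
                blocks.append(fp.transform(C))
        except (SingularFitError, ValueError) as exc:
            raise InvalidParamsError(str(exc)) from exc
        X = np.hstack(blocks)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise InvalidParamsError("FPC score matrix is rank deficient")
        self.model_ = PeakPowerRegressor(
            family=self.family,
            standardize=d.get("standardize", "No") == "Yes",
            lr_reg=d.get("lr_reg", "Ridge"),
            lr_solver=d.get("lr_solver", "Least Squares"),
            lam_lr=d.get("lam_lr", 1e-3),
            svm_kernel=d.get("svm_kernel", "Gaussian"),
            box_constraint=d.get("box_constraint", 1.0),
            kernel_scale=d.get("kernel_scale", 1.0),
            epsilon=d.get("epsilon", 0.1),
            gpr_basis=d.get("gpr_basis", "Constant"),
            gpr_kernel=d.get("gpr_kernel", "Matern 5/2"),
            sigma=d.get("sigma", 0.1),
            random_state=self.random_state,
        ).fit(X, features.y[mask])
        return self

    def transform(self, features: TrialFeatures, mask: np.ndarray | None = None):
        mask = np.ones(features.n_trials, bool) if mask is None else mask
        blocks = [
            fp.transform(sm.transform(curves))
            for curves, sm, fp in zip(
                self._windowed(features, mask), self.smoothers_, self.fpcas_
            )
        ]
        return np.hstack(blocks)

    def predict(self, features: TrialFeatures, mask: np.ndarray | None = None):
        return self.model_.predict(self.transform(features, mask))
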