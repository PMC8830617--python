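"""Seeded generator of synthetic countermovement-jump cohorts.

The generator emulates the statistical structure the modelling pipeline
assumes: cohorts of participants each performing several maximal CMJs with
or without arm swing, recorded as a 1000 Hz vertical ground reaction force
(VGRF, N) and a coupled 250 Hz triaxial accelerometer trace (g) from one of
four sensor sites (lower back LB, upper back UB, left/right shank LS/RS).

The VGRF waveform is a piecewise parametric template — quiet standing, a
half-cosine unweighting dip, a sinusoidal push-off pulse, a cosine-squared
release to zero force, ballistic flight, and a gamma-shaped landing impact
spike whose amplitude is solved so the whole trial's net impulse is zero
(the jumper lands at rest).  The accelerometer is the net VGRF acceleration
resampled to 250 Hz, passed through a site-specific linear distortion
(gain, lag, damped landing resonance) plus white noise, clipped to +/-9 g.

A *linear-link* mode overlays smooth latent bump functions on the signal
and makes the regression target an exact linear function of their
amplitudes — a parameter-recovery surface on which the downstream
FPCA-plus-regression pipeline should attain an error close to the injected
observation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import signals
from .signals import FS_ACCEL, FS_FORCE, G

JUMP_TYPES = ("CMJ_NA", "CMJ_A")
SENSOR_SITES = ("LB", "UB", "LS", "RS")

ACCEL_RANGE_G = 9.0


@dataclass(frozen=True)
class Participant:
    id: str
    body_mass: float  # kg
    group: str        # 'train' or 'holdout'
    n_jumps: int      # total, split equally between jump types
    flight_mu: float = 0.48  # participant-level mean flight time, s

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.n_jumps % 2:
            raise ValueError("n_jumps must be even (split between jump types)")


@dataclass
class Trial:
    trial_id: str
    participant_id: str
    jump_type: str
    sensor_site: str
    vgrf: np.ndarray          # (n,) N at 1000 Hz
    accel: np.ndarray         # (3, m) g at 250 Hz
    body_mass: float          # kg
    latents: np.ndarray | None = None   # linear-link latent amplitudes
    link_target: float | None = None    # linear-link regression target, W/kg
    vgrf_clean: np.ndarray | None = None  # noiseless template (oracle only)


@dataclass
class SiteDistortion:
    """Linear-time-invariant sensor distortion for one anatomical site."""

    gain: float = 1.0
    lag_samples: int = 0          # delay at 250 Hz
    resonance_amp: float = 0.5    # damped oscillation on landing, g
    resonance_freq: float = 12.0  # Hz
    resonance_decay: float = 0.08  # s


DEFAULT_SITES = {
    "LB": SiteDistortion(1.0, 0, 0.4, 12.0, 0.08),
    "UB": SiteDistortion(0.92, 1, 1.2, 9.0, 0.12),
    "LS": SiteDistortion(1.08, 0, 2.5, 22.0, 0.06),
    "RS": SiteDistortion(1.06, 1, 2.2, 20.0, 0.06),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Cohort anthropometrics and flight times follow the recruited cohort
    (body mass 73.1 +/- 13.1 kg; flight time 0.48 +/- 0.066 s, split into
    between- and within-participant components); jumps with arm swing are
    longer (higher peak power).  Waveform shape parameters are chosen so
    the criterion peak power lands in the observed range (CMJ_NA roughly
    45 +/- 7 W/kg).
    """

    n_participants: int = 69
    mass_mean: float = 73.1
    mass_sd: float = 13.1
    mass_min: float = 30.0
    n_holdout: int = 9
    prob_8_jumps: float = 55 / 69  # remainder perform 16
    flight_mean: float = 0.48
    flight_between_sd: float = 0.055
    flight_within_sd: float = 0.036
    cmj_a_flight_bonus: float = 0.045  # arm swing lengthens flight, s
    dip_depth_mean: float = 0.30      # unweighting depth, fraction of BW
    dip_depth_sd: float = 0.06
    dip_duration_mean: float = 0.35   # s
    dip_duration_sd: float = 0.05
    push_duration_mean: float = 0.30  # s
    push_duration_sd: float = 0.04
    release_duration: float = 0.04    # s, force decay to zero at take-off
    stand_pre: float = 1.0            # quiet standing lead-in, s
    stand_post: float = 0.8           # quiet standing tail, s
    landing_duration: float = 0.45    # s
    landing_tau_peak: float = 0.03    # s, impact spike time-to-peak
    landing_tau_ramp: float = 0.012   # s, BW recovery ramp
    noise_sd: float = 0.03            # accelerometer white noise, g
    sites: dict = field(default_factory=lambda: dict(DEFAULT_SITES))
    triaxial_cross_gain: tuple = (0.25, 0.15)
    triaxial_cross_lag: tuple = (2, -2)  # samples at 250 Hz
    # linear-link mode
    linear_link: bool = False
    n_latents: int = 3
    link_coefs: tuple = (5.0, 3.0, 2.0)
    link_intercept: float = 45.0
    link_noise_sd: float = 0.0        # target observation noise, W/kg
    # bumps sit in the push-off phase where the resultant's baseline is well
    # above zero, so their amplitudes pass linearly into the magnitude signal
    link_bump_amp: float = 0.35       # g per latent unit
    link_bump_centres: tuple = (-0.30, -0.22, -0.14)  # s relative to take-off
    link_bump_widths: tuple = (0.05, 0.04, 0.04)      # s
    seed: int = 0


def generate_cohort(config: GeneratorConfig) -> list[Participant]:
    """Draw a cohort of participants: truncated-normal masses, holdout
    assignment and jump counts.  Deterministic given ``config.seed``."""
    if config.n_participants < 2:
        raise ValueError("need at least 2 participants")
    if not 0 <= config.n_holdout < config.n_participants:
        raise ValueError("n_holdout must leave at least one training participant")
    rng = np.random.default_rng(config.seed)
    masses = config.mass_mean + config.mass_sd * rng.standard_normal(config.n_participants)
    while np.any(masses <= config.mass_min):
        bad = masses <= config.mass_min
        masses[bad] = config.mass_mean + config.mass_sd * rng.standard_normal(bad.sum())
    counts = np.where(rng.random(config.n_participants) < config.prob_8_jumps, 8, 16)
    flight_mu = config.flight_mean + config.flight_between_sd * rng.standard_normal(
        config.n_participants
    )
    holdout_ids = rng.choice(config.n_participants, size=config.n_holdout, replace=False)
    holdout = np.zeros(config.n_participants, dtype=bool)
    holdout[holdout_ids] = True
    return [
        Participant(
            id=f"P{k:03d}",
            body_mass=float(masses[k]),
            group="holdout" if holdout[k] else "train",
            n_jumps=int(counts[k]),
            flight_mu=float(np.clip(flight_mu[k], 0.25, 0.75)),
        )
        for k in range(config.n_participants)
    ]


def _vgrf_template(
    body_mass: float,
    flight_time: float,
    dip_depth: float,
    t_dip: float,
    t_push: float,
    config: GeneratorConfig,
) -> tuple[np.ndarray, float]:
    """Piecewise VGRF template; returns (vgrf, takeoff_time).

    The push amplitude is solved so the net impulse up to take-off equals
    m*v_to with v_to = g*T_f/2, and the landing spike amplitude is solved
    so the whole trial's net impulse is zero.
    """
    bw = body_mass * G
    t3 = config.release_duration
    v_to = G * flight_time / 2.0
    a_dip = dip_depth * bw
    # impulse bookkeeping: -A*T1/2 + 2*P*T2/pi - BW*T3/2 = m*v_to
    push_amp = (body_mass * v_to + a_dip * t_dip / 2 + bw * t3 / 2) * np.pi / (2 * t_push)

    dt = 1.0 / FS_FORCE
    n_stand = int(round(config.stand_pre * FS_FORCE))
    n_dip = int(round(t_dip * FS_FORCE))
    n_push = int(round(t_push * FS_FORCE))
    n_rel = int(round(t3 * FS_FORCE))
    # shorten the zero-force segment by the sub-10 N tail of the release so
    # the detected (10 N threshold) flight time matches the configured one
    t_cross = (2 * t3 / np.pi) * np.arccos(np.sqrt(signals.FLIGHT_THRESHOLD_N / bw))
    n_flight = max(1, int(round((flight_time - (t3 - t_cross)) * FS_FORCE)))
    n_land = int(round(config.landing_duration * FS_FORCE))
    n_tail = int(round(config.stand_post * FS_FORCE))

    stand = np.full(n_stand, bw)
    td = np.arange(n_dip) * dt
    dip = bw - a_dip * np.sin(np.pi * td / t_dip) ** 2
    tp = np.arange(n_push) * dt
    push = bw + push_amp * np.sin(np.pi * tp / t_push)
    tr = np.arange(n_rel) * dt
    release = bw * np.cos(np.pi * tr / (2 * t3)) ** 2
    flight = np.zeros(n_flight)

    tl = np.arange(n_land) * dt
    ramp = 1.0 - np.exp(-tl / config.landing_tau_ramp)
    spike_shape = (tl / config.landing_tau_peak) * np.exp(1.0 - tl / config.landing_tau_peak)
    pre_land = np.concatenate([stand, dip, push, release, flight])
    tail = np.full(n_tail, bw)
    # solve spike amplitude so the discrete net impulse over the trial is zero
    deficit = np.trapezoid(bw - pre_land, dx=dt) + np.trapezoid(bw - bw * ramp, dx=dt)
    denom = np.trapezoid(spike_shape, dx=dt)
    spike_amp = deficit / denom
    landing = bw * ramp + spike_amp * spike_shape
    vgrf = np.concatenate([pre_land, landing, tail])
    takeoff_time = (n_stand + n_dip + n_push) * dt + t_cross
    return vgrf, takeoff_time


def _latent_bumps(
    n_samples: int, takeoff_time: float, latents: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    t = np.arange(n_samples) / FS_ACCEL - takeoff_time
    out = np.zeros(n_samples)
    for z, c, w in zip(latents, config.link_bump_centres, config.link_bump_widths):
        out += config.link_bump_amp * z * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def generate_trial(
    participant: Participant,
    jump_type: str,
    sensor_site: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    trial_id: str = "T000",
) -> Trial:
    """One synchronised VGRF + accelerometer trial.

    The accelerometer's vertical channel reads 1 g at quiet standing,
    (VGRF/BW) g during ground contact and 0 g in flight, then the site's
    gain/lag/landing-resonance distortion and white noise are applied; the
    two transverse channels carry attenuated, phase-shifted copies of the
    dynamic component.
    """
    if jump_type not in JUMP_TYPES:
        raise ValueError(f"unknown jump_type {jump_type!r}")
    if sensor_site not in config.sites:
        raise ValueError(f"unknown sensor_site {sensor_site!r}")

    flight_mu = participant.flight_mu + (
        config.cmj_a_flight_bonus if jump_type == "CMJ_A" else 0.0
    )
    for _ in range(100):
        flight = flight_mu + config.flight_within_sd * rng.standard_normal()
        if flight > 0.1:
            break
    else:
        raise ValueError("could not sample a positive flight duration")
    if config.linear_link:
        # recovery surface: freeze the phase-shape nuisance so the latent
        # bumps sit on a stable baseline in take-off-aligned time
        dip_depth = config.dip_depth_mean
        t_dip = config.dip_duration_mean
        t_push = config.push_duration_mean
    else:
        dip_depth = float(np.clip(
            rng.normal(config.dip_depth_mean, config.dip_depth_sd), 0.08, 0.6
        ))
        t_dip = max(0.15, rng.normal(config.dip_duration_mean, config.dip_duration_sd))
        t_push = max(0.15, rng.normal(config.push_duration_mean, config.push_duration_sd))

    vgrf, takeoff_time = _vgrf_template(
        participant.body_mass, flight, dip_depth, t_dip, t_push, config
    )

    bw = participant.body_mass * G
    # vertical accelerometer reading in g: VGRF/BW during contact, 0 in flight
    vert_1k = vgrf / bw
    vert = vert_1k[::4].copy()  # exact decimation 1000 -> 250 Hz

    latents = None
    link_target = None
    if config.linear_link:
        latents = rng.standard_normal(config.n_latents)
        vert = vert + _latent_bumps(vert.size, takeoff_time, latents, config)
        coefs = np.asarray(config.link_coefs)[: config.n_latents]
        link_target = float(config.link_intercept + coefs @ latents)
        if config.link_noise_sd > 0:
            link_target += float(config.link_noise_sd * rng.standard_normal())

    site = config.sites[sensor_site]
    distorted = site.gain * vert
    if site.lag_samples:
        distorted = np.roll(distorted, site.lag_samples)
        distorted[: site.lag_samples] = distorted[site.lag_samples]
    # damped oscillation excited by the landing impact
    _, landing_1k, _ = signals.detect_takeoff_landing(vgrf)
    i_land = landing_1k // 4
    tl = np.arange(vert.size - i_land) / FS_ACCEL
    distorted[i_land:] += (
        site.resonance_amp
        * np.exp(-tl / site.resonance_decay)
        * np.sin(2 * np.pi * site.resonance_freq * tl)
    )

    dynamic = distorted - site.gain  # deviation from the static 1 g baseline
    channels = [distorted]
    for g_cross, lag in zip(config.triaxial_cross_gain, config.triaxial_cross_lag):
        ch = g_cross * np.roll(dynamic, lag)
        if lag > 0:
            ch[:lag] = ch[lag]
        elif lag < 0:
            ch[lag:] = ch[lag - 1]
        channels.append(ch)
    accel = np.stack(channels)
    if config.noise_sd > 0:
        accel = accel + config.noise_sd * rng.standard_normal(accel.shape)
    accel = np.clip(accel, -ACCEL_RANGE_G, ACCEL_RANGE_G)

    vgrf_noisy = vgrf  # force platform treated as noise-free criterion source
    return Trial(
        trial_id=trial_id,
        participant_id=participant.id,
        jump_type=jump_type,
        sensor_site=sensor_site,
        vgrf=vgrf_noisy,
        accel=accel,
        body_mass=participant.body_mass,
        latents=latents,
        link_target=link_target,
        vgrf_clean=vgrf,
    )


def generate_dataset(
    config: GeneratorConfig,
    sensor_site: str = "LB",
    jump_types: tuple[str, ...] = JUMP_TYPES,
) -> tuple[list[Participant], list[Trial]]:
    """Full cohort of trials for one sensor site.  Each participant's jumps
    are split equally between the requested jump types."""
    cohort = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    trials = []
    for p in cohort:
        per_type = p.n_jumps // len(JUMP_TYPES)
        for jt in jump_types:
            for j in range(per_type):
                tid = f"{p.id}_{jt}_{j:02d}"
                trials.append(generate_trial(p, jt, sensor_site, config, rng, tid))
    return cohort, trials


def ground_truth_table(trials: list[Trial]) -> pd.DataFrame:
    """Per-trial criterion peak power (W/kg) and flight time (s).

    Peak power is computed by the criterion operation on the noiseless
    VGRF template; in linear-link mode the stored linear-function target is
    used instead.  This table is the regression target and the recovery
    oracle for downstream models.
    """
    rows = []
    for tr in trials:
        vgrf = tr.vgrf_clean if tr.vgrf_clean is not None else tr.vgrf
        _, _, flight = signals.detect_takeoff_landing(vgrf)
        if tr.link_target is not None:
            power = tr.link_target
        else:
            power = signals.compute_criterion_peak_power(vgrf, tr.body_mass)
        rows.append(
            {
                "trial_id": tr.trial_id,
                "participant_id": tr.participant_id,
                "jump_type": tr.jump_type,
                "peak_power_wkg": power,
                "flight_time_s": flight,
                "body_mass": tr.body_mass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "participant_id", "jump_type",
            "peak_power_wkg", "flight_time_s", "body_mass",
        ],
    )


def write_trials_csv(trials: list[Trial], path) -> None:
    """Long-format dump: one row per (trial, channel, sample)."""
    frames = []
    for tr in trials:
        tv = np.arange(tr.vgrf.size) / FS_FORCE
        frames.append(
            pd.DataFrame(
                {"trial_id": tr.trial_id, "channel": "vgrf", "t": tv, "value": tr.vgrf}
            )
        )
        ta = np.arange(tr.accel.shape[1]) / FS_ACCEL
        for ax, name in enumerate(("accel_x", "accel_y", "accel_z")):
            frames.append(
                pd.DataFrame(
                    {"trial_id": tr.trial_id, "channel": name, "t": ta,
                     "value": tr.accel[ax]}
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(trials_path, manifest_path) -> tuple[list[Participant], list[Trial]]:
    """Read back the long-format trial CSV + JSON manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    participants = [Participant(**p) for p in manifest["participants"]]
    masses = {p.id: p.body_mass for p in participants}
    df = pd.read_csv(trials_path)
    trials = []
    for tid, group in df.groupby("trial_id", sort=False):
        pid, jt_a, jt_b, _ = tid.split("_")
        jump_type = f"{jt_a}_{jt_b}"
        vgrf = group.loc[group.channel == "vgrf", "value"].to_numpy()
        accel = np.stack([
            group.loc[group.channel == ch, "value"].to_numpy()
            for ch in ("accel_x", "accel_y", "accel_z")
        ])
        trials.append(
            Trial(
                trial_id=tid, participant_id=pid, jump_type=jump_type,
                sensor_site=manifest.get("sensor_site", "LB"),
                vgrf=vgrf, accel=accel, body_mass=masses[pid],
            )
        )
    return participants, trials


def write_manifest(participants: list[Participant], config: GeneratorConfig, path,
                   sensor_site: str = "LB") -> None:
    manifest = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "sensor_site": sensor_site,
        "participants": [asdict(p) for p in participants],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
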