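"""Synthetic gap-paradigm sessions with per-trial ground truth.

The generator emulates 250 Hz binocular recordings of the gap protocol:
the subject fixates the central dot, re-fixates it after each trial (a
*return saccade* early in the next central period), and launches a
visually guided saccade toward the eccentric target after a drawn latency.

Kinematic model.  Peak velocity follows a saturating main-sequence law
``Vp = vmax * (1 - exp(-A / a0))`` (defaults vmax = 600 deg/s, a0 = 8 deg,
within the range reported for healthy human saccades).  Each saccade has a
raised-cosine velocity profile ``v(t) = Vp * (1 - cos(2*pi*t/D)) / 2``
with duration ``D = 2A / Vp``, which integrates exactly to the amplitude
and has time-mean velocity Vp/2.

Latency is shifted-gamma distributed (shift 130 ms, shape 4, scale 25 ms:
mean 230 ms, typical of gap-paradigm saccades in older adults); with
probability ``p_anticipatory`` the trial is anticipatory instead, with a
uniform latency below 100 ms.  Gain is Gaussian around 0.9 (hypometria),
truncated to [0.5, 1.3].  Saccade onsets are aligned to the 4 ms sample
clock (the simulation is discrete-time).

Blinks arrive as a Poisson process, with durations uniform in 100-300 ms,
and are realized as both-eyes-invalid runs; they are drawn to avoid
saccade intervals (saccadic blink suppression), which keeps ground-truth
event counts well defined.  Per-eye, per-sample data loss and a fixed
interocular offset exercise the single-eye branches of eye averaging.
Fixational noise is white Gaussian in angle space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import STUDY_DISPLAY, ScreenGeometry
from .io import GazeRecording
from .trials import StimulusProtocol, build_schedule

__all__ = [
    "SimulationParams",
    "GroundTruthTrial",
    "SyntheticCohortSpec",
    "CohortResult",
    "main_sequence",
    "saccade_waveform",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "write_ground_truth_jsonl",
    "read_ground_truth_jsonl",
]


@dataclass(frozen=True)
class SimulationParams:
    """Tunable parameters of the synthetic oculomotor generator."""

    main_sequence_vmax: float = 600.0  # deg/s
    main_sequence_a0: float = 8.0  # deg
    latency_shape: float = 4.0
    latency_scale: float = 25.0  # ms
    latency_shift: float = 130.0  # ms
    gain_mean: float = 0.9
    gain_sd: float = 0.08
    gain_bounds: tuple[float, float] = (0.5, 1.3)
    noise_sd_deg: float = 0.15
    blink_rate_per_min: float = 12.0
    blink_duration_ms_range: tuple[float, float] = (100.0, 300.0)
    p_anticipatory: float = 0.05
    data_loss_rate: float = 0.002  # per eye per sample
    interocular_offset_deg: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "main_sequence_vmax",
            "main_sequence_a0",
            "latency_shape",
            "latency_scale",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"SimulationParams.{name} must be positive")
        for name in ("gain_sd", "noise_sd_deg", "blink_rate_per_min", "data_loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimulationParams.{name} must be non-negative")
        if not (0 < self.gain_mean <= 1.5):
            raise ValueError("gain_mean must lie in (0, 1.5]")
        if not (0 <= self.p_anticipatory <= 1):
            raise ValueError("p_anticipatory must lie in [0, 1]")


@dataclass
class GroundTruthTrial:
    """Sidecar of true kinematics for one simulated trial.

    ``true_duration_ms = 2 * true_amplitude / true_peak_velocity`` holds
    exactly (raised-cosine identity).  ``return_onset_ms``/``return_offset_ms``
    bound the re-fixation saccade made during this trial's central period
    (None for the first trial, which starts at center).  Times are absolute
    ms within the session.
    """

    trial_index: int
    true_latency_ms: float
    true_amplitude_deg: float
    true_peak_velocity_deg_s: float
    true_duration_ms: float
    true_gain: float
    anticipatory: bool
    blink_times: list = field(default_factory=list)
    true_onset_ms: float = 0.0
    true_offset_ms: float = 0.0
    return_onset_ms: Optional[float] = None
    return_offset_ms: Optional[float] = None


def main_sequence(amplitude_deg, params: SimulationParams = SimulationParams()):
    """Saturating amplitude -> peak-velocity law, ``vmax*(1-exp(-A/a0))``."""
    amp = np.asarray(amplitude_deg, dtype=float)
    if np.any(amp <= 0):
        raise ValueError("amplitude must be positive")
    v = params.main_sequence_vmax * (1.0 - np.exp(-amp / params.main_sequence_a0))
    return v if v.ndim else float(v)


def _raised_cosine_frac(tau_ms, duration_ms):
    """Fraction of the amplitude covered after ``tau_ms`` of a raised-cosine
    saccade of ``duration_ms`` (0 before onset, 1 after offset)."""
    tau = np.clip(np.asarray(tau_ms, dtype=float) / duration_ms, 0.0, 1.0)
    return tau - np.sin(2.0 * np.pi * tau) / (2.0 * np.pi)


def saccade_waveform(
    amplitude_deg: float,
    peak_velocity_deg_s: float,
    onset_ms: float = 0.0,
    rate_hz: float = 250.0,
):
    """Sampled position and velocity of one raised-cosine saccade.

    Returns ``(t_ms, position_deg, velocity_deg_s)`` over the saccade
    span ``[onset, onset + D]`` sampled at ``rate_hz``, where
    ``D = 2 * amplitude / peak_velocity``.  The integrated displacement
    equals the amplitude and the time-mean of the velocity profile is
    exactly half the peak velocity.
    """
    if amplitude_deg <= 0 or peak_velocity_deg_s <= 0:
        raise ValueError("amplitude and peak velocity must be positive")
    duration_ms = 2.0 * amplitude_deg / peak_velocity_deg_s * 1000.0
    dt = 1000.0 / rate_hz
    n = int(np.floor(duration_ms / dt)) + 1
    tau = np.arange(n) * dt
    if tau[-1] < duration_ms:  # close the span at the exact offset
        tau = np.append(tau, duration_ms)
    t = onset_ms + tau
    pos = amplitude_deg * _raised_cosine_frac(tau, duration_ms)
    vel = (
        peak_velocity_deg_s
        * (1.0 - np.cos(2.0 * np.pi * np.clip(tau / duration_ms, 0, 1)))
        / 2.0
    )
    return t, pos, vel


def _snap(value_ms: float, dt: float) -> float:
    return math.floor(value_ms / dt) * dt


def _simulate_paths(
    schedule: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator,
    rate_hz: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[GroundTruthTrial], list]:
    """Noiseless cyclopean angle-space path plus ground truth.

    Returns (t_ms, ax_deg, ay_deg, ground_truth, saccade_intervals).
    Angles are signed offsets from the screen-center gaze ray along the
    horizontal/vertical axes.
    """
    dt = 1000.0 / rate_hz
    total_ms = float(schedule["target_offset_ms"].max())
    n = int(round(total_ms / dt))
    t = np.arange(n) * dt
    ax = np.zeros(n)
    ay = np.zeros(n)

    cur = np.zeros(2)
    fill_from = 0  # sample index from which `cur` still needs writing
    truths: list[GroundTruthTrial] = []
    saccade_intervals: list[tuple[float, float]] = []

    def place_saccade(onset_ms: float, start: np.ndarray, end: np.ndarray) -> tuple[float, float]:
        nonlocal fill_from
        amp = float(np.hypot(*(end - start)))
        vp = main_sequence(amp, params)
        dur = 2.0 * amp / vp * 1000.0
        i0 = int(round(onset_ms / dt))
        i1 = min(n, int(np.ceil((onset_ms + dur) / dt)))
        ax[fill_from:i0] = start[0]
        ay[fill_from:i0] = start[1]
        frac = _raised_cosine_frac(t[i0:i1] - onset_ms, dur)
        ax[i0:i1] = start[0] + frac * (end[0] - start[0])
        ay[i0:i1] = start[1] + frac * (end[1] - start[1])
        fill_from = i1
        saccade_intervals.append((onset_ms, onset_ms + dur))
        return vp, dur

    for row in schedule.to_dict("records"):
        # re-fixation of the central dot
        ret: Optional[tuple[float, float]] = None
        if np.hypot(*cur) > 1e-9:
            onset = _snap(
                row["central_onset_ms"] + rng.uniform(100.0, 300.0), dt
            )
            _, dur = place_saccade(onset, cur, np.zeros(2))
            cur = np.zeros(2)
            ret = (onset, onset + dur)

        # primary target-directed saccade
        anticipatory = rng.random() < params.p_anticipatory
        if anticipatory:
            latency = rng.uniform(0.0, 100.0)
        else:
            latency = params.latency_shift + rng.gamma(
                params.latency_shape, params.latency_scale
            )
            latency = min(latency, 1300.0)
        latency = _snap(latency, dt)
        gain = float(
            np.clip(
                rng.normal(params.gain_mean, params.gain_sd), *params.gain_bounds
            )
        )
        amp_signed = row["amplitude_deg"]
        target = (
            np.array([amp_signed, 0.0])
            if row["task"] == "horizontal"
            else np.array([0.0, amp_signed])
        )
        end = gain * target
        onset = row["target_onset_ms"] + latency
        vp, dur = place_saccade(onset, cur, end)
        cur = end

        truths.append(
            GroundTruthTrial(
                trial_index=int(row["trial_index"]),
                true_latency_ms=latency,
                true_amplitude_deg=gain * abs(amp_signed),
                true_peak_velocity_deg_s=vp,
                true_duration_ms=dur,
                true_gain=gain,
                anticipatory=bool(anticipatory),
                true_onset_ms=onset,
                true_offset_ms=onset + dur,
                return_onset_ms=ret[0] if ret else None,
                return_offset_ms=ret[1] if ret else None,
            )
        )

    ax[fill_from:] = cur[0]
    ay[fill_from:] = cur[1]
    return t, ax, ay, truths, saccade_intervals


def _draw_blinks(
    rng: np.random.Generator,
    total_ms: float,
    params: SimulationParams,
    saccade_intervals: list,
    dt: float,
    margin_ms: float = 12.0,
) -> list[tuple[float, float]]:
    """Poisson blink process avoiding saccades (blink suppression)."""
    if params.blink_rate_per_min <= 0:
        return []
    count = rng.poisson(params.blink_rate_per_min * total_ms / 60000.0)
    lo, hi = params.blink_duration_ms_range
    blinks: list[tuple[float, float]] = []
    for _ in range(count):
        for _attempt in range(100):
            dur = _snap(rng.uniform(lo, hi), dt)
            start = _snap(rng.uniform(0.0, total_ms - dur), dt)
            end = start + dur
            clash = any(
                start - margin_ms < s1 and end + margin_ms > s0
                for s0, s1 in saccade_intervals
            ) or any(start - dt < b1 and end + dt > b0 for b0, b1 in blinks)
            if not clash:
                blinks.append((start, end))
                break
    blinks.sort()
    return blinks


def _angles_to_px(a_deg: np.ndarray, axis_center: float, geometry: ScreenGeometry):
    cmpp = geometry.cm_per_px
    return axis_center + np.tan(np.radians(a_deg)) * geometry.viewing_distance_cm / cmpp


def _render_recording(
    t: np.ndarray,
    ax: np.ndarray,
    ay: np.ndarray,
    blinks: list,
    params: SimulationParams,
    rng: np.random.Generator,
    geometry: ScreenGeometry,
    subject_id: str,
    rate_hz: float,
) -> GazeRecording:
    n = len(t)
    nx = ax + rng.normal(0.0, params.noise_sd_deg, n) if params.noise_sd_deg else ax
    ny = ay + rng.normal(0.0, params.noise_sd_deg, n) if params.noise_sd_deg else ay

    half = params.interocular_offset_deg / 2.0
    cx, cy = geometry.center_px
    lx = _angles_to_px(nx - half, cx, geometry)
    rx = _angles_to_px(nx + half, cx, geometry)
    ly = _angles_to_px(ny, cy, geometry)
    ry = ly.copy()

    lval = np.zeros(n, dtype=int)
    rval = np.zeros(n, dtype=int)
    if params.data_loss_rate > 0:
        lval[rng.random(n) < params.data_loss_rate] = 4
        rval[rng.random(n) < params.data_loss_rate] = 4
    for b0, b1 in blinks:
        m = (t >= b0) & (t < b1)
        lval[m] = 4
        rval[m] = 4
    lx[lval != 0] = np.nan
    ly[lval != 0] = np.nan
    rx[rval != 0] = np.nan
    ry[rval != 0] = np.nan

    samples = pd.DataFrame(
        {"t": t, "lx": lx, "ly": ly, "lval": lval, "rx": rx, "ry": ry, "rval": rval}
    )
    return GazeRecording(
        subject_id=subject_id,
        samples=samples,
        nominal_rate_hz=rate_hz,
        geometry=geometry,
    )


def simulate_session(
    protocol: StimulusProtocol,
    params: SimulationParams = SimulationParams(),
    subject_id: str = "sim",
    geometry: ScreenGeometry = STUDY_DISPLAY,
    rate_hz: float = 250.0,
) -> tuple[GazeRecording, pd.DataFrame, list[GroundTruthTrial]]:
    """Simulate one full task session.

    Deterministic given ``params.seed``: the stimulus schedule, kinematic
    draws, blink process, noise and data loss all derive from it.
    """
    schedule = build_schedule(protocol, seed=params.seed, geometry=geometry)
    rng = np.random.default_rng([params.seed, 0x5ACC])
    dt = 1000.0 / rate_hz

    t, ax, ay, truths, saccade_intervals = _simulate_paths(
        schedule, params, rng, rate_hz
    )
    blinks = _draw_blinks(rng, float(t[-1] + dt), params, saccade_intervals, dt)
    for gt in truths:
        row = schedule.iloc[gt.trial_index]
        gt.blink_times = [
            [b0, b1]
            for b0, b1 in blinks
            if row["central_onset_ms"] <= b0 < row["target_offset_ms"]
        ]
    recording = _render_recording(
        t, ax, ay, blinks, params, rng, geometry, subject_id, rate_hz
    )
    return recording, schedule, truths


def simulate_trial(
    stimulus: dict,
    params: SimulationParams = SimulationParams(),
    rng: Optional[np.random.Generator] = None,
    geometry: ScreenGeometry = STUDY_DISPLAY,
    rate_hz: float = 250.0,
) -> tuple[GazeRecording, GroundTruthTrial]:
    """Simulate a single trial starting from central fixation.

    ``stimulus`` is one row of a schedule (as a mapping).  Useful for
    focused round-trip tests; sessions should use :func:`simulate_session`.
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 0x731A])
    sched = pd.DataFrame([dict(stimulus)])
    offset = float(sched.loc[0, "central_onset_ms"])
    for col in (
        "central_onset_ms",
        "central_offset_ms",
        "target_onset_ms",
        "target_offset_ms",
    ):
        sched[col] = sched[col] - offset
    dt = 1000.0 / rate_hz
    t, ax, ay, truths, saccade_intervals = _simulate_paths(
        sched, params, rng, rate_hz
    )
    blinks = _draw_blinks(rng, float(t[-1] + dt), params, saccade_intervals, dt)
    truths[0].blink_times = [[b0, b1] for b0, b1 in blinks]
    recording = _render_recording(
        t, ax, ay, blinks, params, rng, geometry, "sim-trial", rate_hz
    )
    return recording, truths[0]


def write_ground_truth_jsonl(truths: list[GroundTruthTrial], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gt in truths:
            fh.write(json.dumps(asdict(gt)) + "\n")


def read_ground_truth_jsonl(path) -> list[GroundTruthTrial]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(GroundTruthTrial(**json.loads(line)))
    return out


# ---------------------------------------------------------------------------
# synthetic clinical cohort


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort generator: covariates plus covariate->kinematics couplings.

    ``effects`` maps a metric name to ``{covariate: slope}``; each
    subject's true metric mean is ``baseline + sum(slope * centered
    covariate) + Normal(0, residual_sd)``.  With all slopes zero the
    covariate-metric pairs are exchangeable (the null cohort).

    Demographic defaults emulate a moderate PD cohort: 62 subjects,
    37:25 male:female, age ~ N(60.4, 9.0) years, Hoehn & Yahr stages
    concentrated around 2, MMSE available for 42 subjects and CANTAB for
    22 (CANTAB nested within the MMSE subset by default).
    """

    n_subjects: int = 62
    age_mean: float = 60.35
    age_sd: float = 8.98
    age_range: tuple[float, float] = (38.0, 85.0)
    sex_ratio: tuple[int, int] = (37, 25)  # male, female
    hy_stage_probs: dict = field(
        default_factory=lambda: {
            1.0: 3 / 62,
            1.5: 12 / 62,
            2.0: 29 / 62,
            2.5: 6 / 62,
            3.0: 6 / 62,
            4.0: 6 / 62,
        }
    )
    n_mmse: int = 42
    n_cantab: int = 22
    cantab_nested: bool = True
    baselines: dict = field(
        default_factory=lambda: {
            "latency_ms": 230.0,
            "duration_ms": 46.0,
            "amplitude_deg": 9.0,
            "mean_velocity_deg_s": 200.0,
            "peak_velocity_deg_s": 420.0,
            "gain": 0.9,
            "blink_rate": 12.0,
            "percent_valid": 90.0,
        }
    )
    residual_sd: dict = field(
        default_factory=lambda: {
            "latency_ms": 20.0,
            "duration_ms": 5.0,
            "amplitude_deg": 0.8,
            "mean_velocity_deg_s": 25.0,
            "peak_velocity_deg_s": 40.0,
            "gain": 0.08,
            "blink_rate": 4.0,
            "percent_valid": 8.0,
        }
    )
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(sd < 0 for sd in self.residual_sd.values()):
            raise ValueError("residual SDs must be non-negative")
        if self.n_mmse > self.n_subjects or self.n_cantab > self.n_subjects:
            raise ValueError("score subset sizes cannot exceed n_subjects")


@dataclass
class CohortResult:
    clinical: pd.DataFrame
    metrics: pd.DataFrame
    sessions: Optional[dict] = None

    def merged(self) -> pd.DataFrame:
        return self.clinical.merge(self.metrics, on="subject_id")


_CLINICAL_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "hy_stage",
    "disease_duration_yr",
    "mmse",
    "cantab_prmcd",
    "cantab_prmmcld",
    "cantab_prmpci",
    "cantab_prmmcli",
    "cantab_swm_te",
]


def simulate_cohort(
    spec: SyntheticCohortSpec = SyntheticCohortSpec(),
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
    simulate_gaze: bool = False,
    protocols: tuple[StimulusProtocol, ...] = (),
) -> CohortResult:
    """Draw a synthetic clinical table plus per-subject oculomotor metrics.

    The fast default only draws the covariates and the per-subject true
    metric means (sufficient for correlation calibration).  With
    ``simulate_gaze=True``, full gaze sessions are additionally simulated
    for each subject and protocol, with the subject's latency mean, gain
    and blink rate injected into the session parameters.
    """
    rng = np.random.default_rng([seed, 0xC040])
    n = spec.n_subjects
    ids = [f"S{i + 1:03d}" for i in range(n)]

    m, f = spec.sex_ratio
    n_male = int(round(n * m / (m + f)))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    lo, hi = spec.age_range
    for _ in range(100):
        bad = (age < lo) | (age > hi)
        if not bad.any():
            break
        age[bad] = rng.normal(spec.age_mean, spec.age_sd, int(bad.sum()))
    age = np.round(np.clip(age, lo, hi), 1)

    stages = np.array(list(spec.hy_stage_probs))
    probs = np.array(list(spec.hy_stage_probs.values()), dtype=float)
    hy = rng.choice(stages, size=n, p=probs / probs.sum())

    duration = np.round(np.clip(rng.gamma(2.0, 3.0, n), 0.5, 25.0), 1)

    mmse_idx = rng.choice(n, size=spec.n_mmse, replace=False)
    mmse = np.full(n, np.nan)
    mmse[mmse_idx] = np.clip(np.round(rng.normal(28.0, 2.61, spec.n_mmse)), 0, 30)

    pool = mmse_idx if spec.cantab_nested and spec.n_cantab <= spec.n_mmse else np.arange(n)
    cantab_idx = rng.choice(pool, size=spec.n_cantab, replace=False)
    cantab = {
        "cantab_prmcd": (0.77, 0.12, (0.0, 1.0)),
        "cantab_prmmcld": (2631.86, 560.96, (200.0, None)),
        "cantab_prmpci": (8.36, 24.33, (0.0, None)),
        "cantab_prmmcli": (2529.89, 652.80, (200.0, None)),
        "cantab_swm_te": (23.23, 8.33, (0.0, None)),
    }
    cantab_cols = {}
    for colname, (mu, sd, bounds) in cantab.items():
        vals = np.full(n, np.nan)
        draw = rng.normal(mu, sd, spec.n_cantab)
        lo_b, hi_b = bounds
        draw = np.clip(draw, lo_b, hi_b if hi_b is not None else np.inf)
        vals[cantab_idx] = np.round(draw, 2)
        cantab_cols[colname] = vals

    clinical = pd.DataFrame(
        {
            "subject_id": ids,
            "age": age,
            "sex": sex,
            "hy_stage": hy,
            "disease_duration_yr": duration,
            "mmse": mmse,
            **cantab_cols,
        }
    )[_CLINICAL_COLUMNS]

    # per-subject metric means: baseline + effects x centered covariates + residual
    metrics = pd.DataFrame({"subject_id": ids})
    for metric, base in spec.baselines.items():
        val = np.full(n, float(base))
        for cov, slope in spec.effects.get(metric, {}).items():
            cov_vals = clinical[cov].to_numpy(float)
            center = np.nanmean(cov_vals)
            val = val + slope * np.nan_to_num(cov_vals - center)
        sd = spec.residual_sd.get(metric, 0.0)
        if sd > 0:
            val = val + rng.normal(0.0, sd, n)
        if metric == "percent_valid":
            val = np.clip(val, 0.0, 100.0)
        elif metric == "gain":
            val = np.clip(val, 0.05, 1.5)
        elif metric == "latency_ms":
            val = np.clip(val, 105.0, 1000.0)
        else:
            val = np.clip(val, 0.0, None)
        metrics[metric] = val

    sessions = None
    if simulate_gaze:
        if not protocols:
            protocols = (StimulusProtocol.horizontal(), StimulusProtocol.vertical())
        sessions = {}
        from dataclasses import replace

        for i, sid in enumerate(ids):
            subj_seed = int((seed * 100003 + i * 97 + 13) % (2**31 - 1))
            subj_params = replace(
                params,
                latency_shift=max(
                    100.0,
                    float(metrics.loc[i, "latency_ms"])
                    - params.latency_shape * params.latency_scale,
                ),
                gain_mean=float(np.clip(metrics.loc[i, "gain"], 0.5, 1.3)),
                blink_rate_per_min=float(metrics.loc[i, "blink_rate"]),
                seed=subj_seed,
            )
            for proto in protocols:
                sessions[(sid, proto.task)] = simulate_session(
                    proto, subj_params, subject_id=sid
                )
    return CohortResult(clinical=clinical, metrics=metrics, sessions=sessions)
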