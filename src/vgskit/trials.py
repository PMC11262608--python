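"""Gap-paradigm stimulus schedules, trial validity, and saccadic metrics.

A trial is 1500 ms of central fixation dot, a 200 ms gap with no stimulus,
then an eccentric target for 1500 ms (3200 ms total).  Horizontal sessions
present targets at +-10 and +-18 degrees (classes *near*/*far*), vertical
sessions at +-8 degrees along the vertical meridian (classes *up*/*down*;
screen-y grows downward, so *up* is the negative amplitude).

Validity of a trial requires, in order: (a) no saccade or blink in the
60 ms before the central dot disappears, (b) gaze within 100 px of the
screen center at that moment, and (c) a first saccade leaving that
starting region with a latency in [100, 1500) ms after target onset.
Saccades launched earlier than 100 ms are anticipatory (pre-planned rather
than stimulus-driven) and invalidate the trial.  Subjects contribute to
group statistics only with at least 6 valid trials per task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .events import EventDetectionResult, GazeEvent, IVTParams, detect_events
from .geometry import (
    STUDY_DISPLAY,
    ScreenGeometry,
    angular_distance_deg,
    degrees_to_pixels,
)
from .io import GazeRecording

__all__ = [
    "StimulusProtocol",
    "TrialValidityParams",
    "SaccadeMetrics",
    "Trial",
    "SubjectSummary",
    "build_schedule",
    "segment_trials",
    "validate_trial",
    "select_first_saccade",
    "compute_saccade_metrics",
    "blink_rate",
    "aggregate_subject",
    "analyze_session",
    "trials_to_frame",
    "METRIC_FIELDS",
]

METRIC_FIELDS = (
    "latency_ms",
    "duration_ms",
    "amplitude_deg",
    "mean_velocity_deg_s",
    "peak_velocity_deg_s",
    "gain",
)


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing and amplitude layout of one VGS task."""

    task: str  # horizontal | vertical
    central_ms: float = 1500.0
    gap_ms: float = 200.0
    target_ms: float = 1500.0
    amplitudes_deg: tuple[float, ...] = (-18.0, -10.0, 10.0, 18.0)
    reps_per_amplitude: int = 10

    def __post_init__(self) -> None:
        if self.task not in ("horizontal", "vertical"):
            raise ValueError("task must be 'horizontal' or 'vertical'")
        if not self.amplitudes_deg:
            raise ValueError("amplitudes_deg must be non-empty")

    @property
    def trial_period_ms(self) -> float:
        return self.central_ms + self.gap_ms + self.target_ms

    @property
    def n_trials(self) -> int:
        return len(self.amplitudes_deg) * self.reps_per_amplitude

    @classmethod
    def horizontal(cls) -> "StimulusProtocol":
        return cls(task="horizontal")

    @classmethod
    def vertical(cls, reps_per_amplitude: int = 20) -> "StimulusProtocol":
        # 40 presentations per task: 20 per amplitude over the two
        # vertical eccentricities (-8 up, +8 down in screen-y convention)
        return cls(
            task="vertical",
            amplitudes_deg=(-8.0, 8.0),
            reps_per_amplitude=reps_per_amplitude,
        )


@dataclass(frozen=True)
class TrialValidityParams:
    pre_offset_exclusion_ms: float = 60.0
    start_radius_px: float = 100.0
    min_latency_ms: float = 100.0
    max_latency_ms: float = 1500.0
    min_valid_trials: int = 6


@dataclass(frozen=True)
class SaccadeMetrics:
    """The six per-trial saccadic parameters.

    gain = saccade amplitude / |target amplitude|; velocities in deg/s.
    """

    latency_ms: float
    duration_ms: float
    amplitude_deg: float
    mean_velocity_deg_s: float
    peak_velocity_deg_s: float
    gain: float


@dataclass
class Trial:
    stimulus: dict
    events: list[GazeEvent]
    verdict: Optional[str] = None  # valid | invalid
    invalid_reason: Optional[str] = None
    metrics: Optional[SaccadeMetrics] = None
    saccade: Optional[GazeEvent] = None


def _eccentricity_class(task: str, amplitudes: tuple[float, ...], amp: float) -> str:
    if task == "vertical":
        return "up" if amp < 0 else "down"
    mags = sorted({abs(a) for a in amplitudes})
    return "near" if abs(amp) <= mags[0] else "far"


def build_schedule(
    protocol: StimulusProtocol,
    seed: int,
    geometry: ScreenGeometry = STUDY_DISPLAY,
) -> pd.DataFrame:
    """Randomized trial order for one task, timed back-to-back.

    Each amplitude appears ``reps_per_amplitude`` times in a uniformly
    random permutation determined by ``seed``.  Target pixel positions are
    placed along the task axis through the screen center.
    """
    rng = np.random.default_rng(seed)
    amps = np.repeat(protocol.amplitudes_deg, protocol.reps_per_amplitude)
    amps = amps[rng.permutation(len(amps))]
    period = protocol.trial_period_ms
    cx, cy = geometry.center_px

    rows = []
    for k, amp in enumerate(amps):
        off = math.copysign(degrees_to_pixels(abs(amp), geometry), amp)
        tx, ty = (cx + off, cy) if protocol.task == "horizontal" else (cx, cy + off)
        t0 = k * period
        rows.append(
            {
                "trial_index": k,
                "task": protocol.task,
                "amplitude_deg": float(amp),
                "eccentricity_class": _eccentricity_class(
                    protocol.task, protocol.amplitudes_deg, amp
                ),
                "central_onset_ms": t0,
                "central_offset_ms": t0 + protocol.central_ms,
                "target_onset_ms": t0 + protocol.central_ms + protocol.gap_ms,
                "target_offset_ms": t0 + period,
                "target_x_px": tx,
                "target_y_px": ty,
            }
        )
    return pd.DataFrame(rows)


def segment_trials(
    recording: GazeRecording,
    schedule: pd.DataFrame,
    events: list[GazeEvent],
) -> list[Trial]:
    """One Trial per stimulus, holding the events overlapping its span."""
    t = recording.samples["t"].to_numpy(float)
    t_last = t[-1] + recording.sample_period_ms if len(t) else 0.0
    missing = schedule.loc[
        schedule["target_offset_ms"] > t_last + 1e-9, "trial_index"
    ].tolist()
    if missing:
        raise ValueError(
            f"recording ends before the schedule; missing trial(s) {missing}"
        )
    trials = []
    for row in schedule.to_dict("records"):
        span = [
            e
            for e in events
            if e.t_end > row["central_onset_ms"] and e.t_start < row["target_offset_ms"]
        ]
        trials.append(Trial(stimulus=row, events=span))
    return trials


def _gaze_at(
    cyclopean: pd.DataFrame, when_ms: float, tol_ms: float = 20.0
) -> Optional[tuple[float, float]]:
    """Cyclopean position at (or at the last sample before) ``when_ms``."""
    t = cyclopean["t"].to_numpy(float)
    i = int(np.searchsorted(t, when_ms, side="right")) - 1
    if i < 0 or when_ms - t[i] > tol_ms:
        return None
    x = float(cyclopean["x"].iloc[i])
    y = float(cyclopean["y"].iloc[i])
    if not (np.isfinite(x) and np.isfinite(y)):
        return None
    return (x, y)


def select_first_saccade(
    trial: Trial,
    params: TrialValidityParams = TrialValidityParams(),
    geometry: ScreenGeometry = STUDY_DISPLAY,
) -> Optional[GazeEvent]:
    """Earliest saccade after target onset that leaves the starting region.

    Only saccades whose start position lies within ``start_radius_px`` of
    the screen center qualify; returns None when no such saccade begins
    before the target disappears.
    """
    cx, cy = geometry.center_px
    onset = trial.stimulus["target_onset_ms"]
    offset = trial.stimulus["target_offset_ms"]
    for e in trial.events:
        if e.kind != "saccade" or e.t_start < onset or e.t_start >= offset:
            continue
        if e.x_start is None or not np.isfinite(e.x_start):
            continue
        if math.hypot(e.x_start - cx, e.y_start - cy) <= params.start_radius_px:
            return e
    return None


def compute_saccade_metrics(
    saccade: GazeEvent,
    cyclopean: pd.DataFrame,
    velocity: np.ndarray,
    stimulus: dict,
    geometry: ScreenGeometry = STUDY_DISPLAY,
) -> SaccadeMetrics:
    """The six saccadic parameters for a selected first saccade.

    Amplitude is the full 2-D angular displacement between gaze at saccade
    start and end; mean/peak velocity are taken over the velocity-trace
    samples inside the saccade span.
    """
    if not saccade.t_end > saccade.t_start:
        raise ValueError("zero-duration saccade")
    t = cyclopean["t"].to_numpy(float)
    m = (t >= saccade.t_start) & (t < saccade.t_end)
    v = velocity[m]
    v = v[np.isfinite(v)]
    amplitude = angular_distance_deg(
        saccade.x_start, saccade.y_start, saccade.x_end, saccade.y_end, geometry
    )
    return SaccadeMetrics(
        latency_ms=saccade.t_start - stimulus["target_onset_ms"],
        duration_ms=saccade.duration_ms,
        amplitude_deg=amplitude,
        mean_velocity_deg_s=float(np.mean(v)) if len(v) else float("nan"),
        peak_velocity_deg_s=float(np.max(v)) if len(v) else float("nan"),
        gain=amplitude / abs(stimulus["amplitude_deg"]),
    )


def validate_trial(
    trial: Trial,
    params: TrialValidityParams = TrialValidityParams(),
    geometry: ScreenGeometry = STUDY_DISPLAY,
    cyclopean: Optional[pd.DataFrame] = None,
    velocity: Optional[np.ndarray] = None,
) -> Trial:
    """Apply the validity checks in order and attach metrics when valid.

    Check order: (a) pre-offset saccade/blink exclusion window, (b) gaze
    within the start radius at central-dot offset, (c) first-saccade
    latency window.  The first failed check is recorded as the single
    ``invalid_reason``.
    """
    stim = trial.stimulus
    c_off = stim["central_offset_ms"]
    w0 = c_off - params.pre_offset_exclusion_ms

    # (a) no saccade or blink overlapping [central_offset - 60, central_offset)
    for e in trial.events:
        if e.kind in ("saccade", "blink") and e.t_end > w0 and e.t_start < c_off:
            trial.verdict = "invalid"
            trial.invalid_reason = (
                "pre_offset_saccade" if e.kind == "saccade" else "pre_offset_blink"
            )
            return trial

    # (b) gaze near the center at central-dot offset
    if cyclopean is not None:
        pos = _gaze_at(cyclopean, c_off)
        if pos is None:
            trial.verdict = "invalid"
            trial.invalid_reason = "tracking_loss"
            return trial
        cx, cy = geometry.center_px
        if math.hypot(pos[0] - cx, pos[1] - cy) > params.start_radius_px:
            trial.verdict = "invalid"
            trial.invalid_reason = "off_center_start"
            return trial

    # (c) first saccade within the latency window
    sacc = select_first_saccade(trial, params, geometry)
    if sacc is None:
        trial.verdict = "invalid"
        trial.invalid_reason = "no_saccade"
        return trial
    latency = sacc.t_start - stim["target_onset_ms"]
    if latency < params.min_latency_ms:
        trial.verdict = "invalid"
        trial.invalid_reason = "anticipatory"
        return trial
    if latency >= params.max_latency_ms:
        trial.verdict = "invalid"
        trial.invalid_reason = "no_saccade"
        return trial

    trial.verdict = "valid"
    trial.invalid_reason = None
    trial.saccade = sacc
    if cyclopean is not None and velocity is not None:
        trial.metrics = compute_saccade_metrics(
            sacc, cyclopean, velocity, stim, geometry
        )
    return trial


def blink_rate(blinks: list[GazeEvent], task_span_ms: float) -> float:
    """Blinks per minute over a task span."""
    if not task_span_ms > 0:
        raise ValueError("task_span_ms must be positive")
    return len(blinks) * 60000.0 / task_span_ms


@dataclass
class SubjectSummary:
    """Per-subject aggregates: per task x eccentricity class mean/SD of
    each saccadic parameter, percent of valid trials, blink rate, and the
    minimum-valid-trials inclusion flag (all keyed per task)."""

    subject_id: str
    by_class: pd.DataFrame
    percent_valid: dict = field(default_factory=dict)
    blink_rate: dict = field(default_factory=dict)
    included: dict = field(default_factory=dict)

    def metric_row(self) -> dict:
        """Flat mapping for correlation grids, e.g. ``horizontal_near_latency_ms``."""
        row: dict = {"subject_id": self.subject_id}
        for rec in self.by_class.to_dict("records"):
            prefix = f"{rec['task']}_{rec['eccentricity_class']}"
            for m in METRIC_FIELDS:
                row[f"{prefix}_{m}"] = rec[f"{m}_mean"]
        for task, v in self.percent_valid.items():
            row[f"{task}_percent_valid"] = v
        for task, v in self.blink_rate.items():
            row[f"{task}_blink_rate"] = v
        return row


def aggregate_subject(
    trials: list[Trial],
    blink_rate_by_task: dict,
    params: TrialValidityParams = TrialValidityParams(),
    subject_id: str = "unknown",
) -> SubjectSummary:
    """Aggregate validated trials into a SubjectSummary.

    Means and sample SDs (n-1 denominator) are computed over valid trials
    per task and eccentricity class; ``included`` is set per task by the
    minimum-valid-trials rule (inclusive at the minimum).
    """
    rows = []
    for tr in trials:
        stim = tr.stimulus
        row = {
            "task": stim["task"],
            "trial_index": stim["trial_index"],
            "eccentricity_class": stim["eccentricity_class"],
            "verdict": tr.verdict,
        }
        if tr.metrics is not None:
            for m in METRIC_FIELDS:
                row[m] = getattr(tr.metrics, m)
        rows.append(row)
    df = pd.DataFrame(rows)

    by_class_rows = []
    percent_valid: dict = {}
    included: dict = {}
    for task, task_df in df.groupby("task"):
        n_valid = int((task_df["verdict"] == "valid").sum())
        percent_valid[task] = 100.0 * n_valid / len(task_df)
        included[task] = n_valid >= params.min_valid_trials
        for cls, cls_df in task_df.groupby("eccentricity_class"):
            valid = cls_df[cls_df["verdict"] == "valid"]
            rec = {
                "task": task,
                "eccentricity_class": cls,
                "n_trials": len(cls_df),
                "n_valid": len(valid),
            }
            for m in METRIC_FIELDS:
                vals = valid[m].to_numpy(float) if m in valid else np.array([])
                rec[f"{m}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
                rec[f"{m}_sd"] = (
                    float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
                )
            by_class_rows.append(rec)

    return SubjectSummary(
        subject_id=subject_id,
        by_class=pd.DataFrame(by_class_rows),
        percent_valid=percent_valid,
        blink_rate=dict(blink_rate_by_task),
        included=included,
    )


def trials_to_frame(trials: list[Trial], subject_id: str = "unknown") -> pd.DataFrame:
    """Trial-level export table."""
    rows = []
    for tr in trials:
        stim = tr.stimulus
        row = {
            "subject_id": subject_id,
            "task": stim["task"],
            "trial_index": stim["trial_index"],
            "eccentricity_class": stim["eccentricity_class"],
            "verdict": tr.verdict,
            "invalid_reason": tr.invalid_reason,
        }
        for m in METRIC_FIELDS:
            row[m] = getattr(tr.metrics, m) if tr.metrics is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SessionResult:
    """Trial-level analysis of one recording against one schedule."""

    trials: list[Trial]
    detection: EventDetectionResult
    blink_rate_per_min: float

    @property
    def trial_frame(self) -> pd.DataFrame:
        return trials_to_frame(self.trials)

    @property
    def n_valid(self) -> int:
        return sum(1 for t in self.trials if t.verdict == "valid")


def analyze_session(
    recording: GazeRecording,
    schedule: pd.DataFrame,
    ivt_params: IVTParams = IVTParams(),
    validity_params: TrialValidityParams = TrialValidityParams(),
) -> SessionResult:
    """Detection + segmentation + validation + metrics for one session."""
    det = detect_events(recording, ivt_params)
    trials = segment_trials(recording, schedule, det.events)
    for tr in trials:
        validate_trial(
            tr, validity_params, recording.geometry, det.cyclopean, det.velocity
        )
    span = float(
        schedule["target_offset_ms"].max() - schedule["central_onset_ms"].min()
    )
    return SessionResult(trials, det, blink_rate(det.blinks, span))
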