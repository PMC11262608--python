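"""Reading and writing the tab-separated gaze-sample dialect.

The dialect mirrors a Tobii-Studio-style export: one header row, tab
separated, UTF-8, with columns ``RecordingTimestamp`` (ms),
``GazePointXLeft``, ``GazePointYLeft``, ``ValidityLeft``,
``GazePointXRight``, ``GazePointYRight``, ``ValidityRight``.  Validity 0
means the eye was tracked with high confidence; any nonzero code marks the
sample invalid (the simulator writes 4 for "eye not found").  Coordinate
cells may be empty only on invalid samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import STUDY_DISPLAY, ScreenGeometry

__all__ = [
    "GAZE_TSV_COLUMNS",
    "GazeRecording",
    "SamplingReport",
    "read_gaze_tsv",
    "write_gaze_tsv",
    "check_sampling",
]

logger = logging.getLogger(__name__)

GAZE_TSV_COLUMNS = (
    "RecordingTimestamp",
    "GazePointXLeft",
    "GazePointYLeft",
    "ValidityLeft",
    "GazePointXRight",
    "GazePointYRight",
    "ValidityRight",
)

#: internal column names, in file order
_SAMPLE_COLUMNS = ("t", "lx", "ly", "lval", "rx", "ry", "rval")


class GazeFormatError(ValueError):
    """Raised when a gaze TSV file violates the dialect."""


@dataclass
class GazeRecording:
    """Ordered binocular gaze samples for one subject.

    ``samples`` is a DataFrame with columns ``t`` (ms since recording
    start), ``lx, ly, rx, ry`` (screen px, NaN when missing) and
    ``lval, rval`` (integer validity, 0 = valid).
    """

    subject_id: str
    samples: pd.DataFrame
    nominal_rate_hz: float = 250.0
    geometry: ScreenGeometry = field(default_factory=lambda: STUDY_DISPLAY)

    def __post_init__(self) -> None:
        missing = [c for c in _SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"samples missing columns: {missing}")
        t = self.samples["t"].to_numpy(dtype=float)
        if len(t) and (not np.all(np.isfinite(t)) or np.any(t < 0)):
            raise ValueError("timestamps must be finite and non-negative")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(
                    f"timestamps not strictly increasing at row {i + 1}"
                )
            med = float(np.median(dt))
            nominal = 1000.0 / self.nominal_rate_hz
            if abs(med - nominal) > 0.1 * nominal:
                # check_sampling() is the designated rate checker; do not
                # refuse to hold off-rate data, just note it.
                logger.warning(
                    "median inter-sample interval %.3f ms deviates >10%% "
                    "from nominal %.3f ms",
                    med,
                    nominal,
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_ms(self) -> float:
        if len(self.samples) < 2:
            return 0.0
        t = self.samples["t"].to_numpy()
        return float(t[-1] - t[0])

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.nominal_rate_hz


@dataclass(frozen=True)
class SamplingReport:
    rate_hz_estimate: float
    gap_count: int
    dropped_fraction: float
    flagged: bool


def read_gaze_tsv(
    path,
    subject_id: str = "unknown",
    geometry: ScreenGeometry = STUDY_DISPLAY,
    nominal_rate_hz: float = 250.0,
) -> GazeRecording:
    """Read a gaze TSV export into a :class:`GazeRecording`.

    Malformed rows (unparseable timestamps) are dropped, counted and
    logged.  A coordinate that is absent while its validity code is 0 is
    inconsistent with the dialect; such samples are coerced to invalid
    (code 4) and logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GAZE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"missing mandatory column(s): {missing}")
    df = df[list(GAZE_TSV_COLUMNS)]
    df.columns = list(_SAMPLE_COLUMNS)

    out = pd.DataFrame(index=df.index)
    for col in ("t", "lx", "ly", "rx", "ry"):
        out[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    for col in ("lval", "rval"):
        v = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        out[col] = v.fillna(4).astype(int)
    out = out[list(_SAMPLE_COLUMNS)]

    bad_time = out["t"].isna()
    if bad_time.any():
        logger.warning(
            "%s: dropped %d malformed row(s) with unparseable timestamps",
            path,
            int(bad_time.sum()),
        )
        out = out.loc[~bad_time].reset_index(drop=True)

    t = out["t"].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            # bad[0] indexes the interval; the offending sample is the next
            # row, +2 more for the header line and 1-based file rows
            raise GazeFormatError(
                f"non-monotone timestamps: row {int(bad[0]) + 3} does not "
                "increase over its predecessor"
            )

    # coordinates absent while validity claims valid -> coerce to invalid
    for xc, yc, vc in (("lx", "ly", "lval"), ("rx", "ry", "rval")):
        incons = (out[xc].isna() | out[yc].isna()) & (out[vc] == 0)
        if incons.any():
            logger.warning(
                "%s: %d sample(s) with blank coordinates but validity 0; "
                "coerced to invalid",
                path,
                int(incons.sum()),
            )
            out.loc[incons, vc] = 4

    return GazeRecording(
        subject_id=subject_id,
        samples=out,
        nominal_rate_hz=nominal_rate_hz,
        geometry=geometry,
    )


def _fmt(value: float) -> str:
    if np.isnan(value):
        return ""
    return repr(float(value))


def write_gaze_tsv(recording: GazeRecording, path) -> None:
    """Write a recording in the gaze TSV dialect (bit-stable output)."""
    s = recording.samples
    lines = ["\t".join(GAZE_TSV_COLUMNS)]
    t = s["t"].to_numpy(float)
    lx = s["lx"].to_numpy(float)
    ly = s["ly"].to_numpy(float)
    rx = s["rx"].to_numpy(float)
    ry = s["ry"].to_numpy(float)
    lval = s["lval"].to_numpy(int)
    rval = s["rval"].to_numpy(int)
    for i in range(len(s)):
        lines.append(
            "\t".join(
                (
                    _fmt(t[i]),
                    _fmt(lx[i]),
                    _fmt(ly[i]),
                    str(lval[i]),
                    _fmt(rx[i]),
                    _fmt(ry[i]),
                    str(rval[i]),
                )
            )
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def check_sampling(recording: GazeRecording) -> SamplingReport:
    """Estimate the effective sampling rate and count timing gaps.

    The rate estimate is ``1000 / median inter-sample interval``; an
    interval longer than 1.5 nominal periods counts as a gap.  The
    recording is flagged when the estimate deviates more than 10% from the
    nominal rate.
    """
    t = recording.samples["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("check_sampling requires at least 2 samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    rate = 1000.0 / med
    nominal_dt = 1000.0 / recording.nominal_rate_hz
    gap_count = int(np.sum(dt > 1.5 * nominal_dt))
    expected = (t[-1] - t[0]) / nominal_dt + 1
    dropped = max(0.0, 1.0 - len(t) / expected)
    flagged = abs(rate - recording.nominal_rate_hz) > 0.1 * recording.nominal_rate_hz
    return SamplingReport(rate, gap_count, float(dropped), bool(flagged))
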