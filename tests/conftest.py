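import numpy as np
import pandas as pd
import pytest

from vgskit import GazeRecording, ScreenGeometry, degrees_to_pixels


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


def make_recording(
    t,
    x_px,
    y_px,
    lval=None,
    rval=None,
    rate_hz: float = 250.0,
    geometry: ScreenGeometry | None = None,
) -> GazeRecording:
    """Binocular recording with both eyes at the given cyclopean path."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x_px, dtype=float)
    y = np.asarray(y_px, dtype=float)
    lval = np.zeros(len(t), dtype=int) if lval is None else np.asarray(lval, int)
    rval = np.zeros(len(t), dtype=int) if rval is None else np.asarray(rval, int)
    lx, ly = x.copy(), y.copy()
    rx, ry = x.copy(), y.copy()
    lx[lval != 0] = np.nan
    ly[lval != 0] = np.nan
    rx[rval != 0] = np.nan
    ry[rval != 0] = np.nan
    samples = pd.DataFrame(
        {"t": t, "lx": lx, "ly": ly, "lval": lval, "rx": rx, "ry": ry, "rval": rval}
    )
    return GazeRecording(
        subject_id="test",
        samples=samples,
        nominal_rate_hz=rate_hz,
        geometry=geometry or ScreenGeometry(),
    )


def center_path(n: int, geometry: ScreenGeometry | None = None, dt: float = 4.0):
    """n samples of steady central fixation."""
    g = geometry or ScreenGeometry()
    cx, cy = g.center_px
    t = np.arange(n) * dt
    return t, np.full(n, cx), np.full(n, cy)


def deg_offset_x(angle_deg: float, geometry: ScreenGeometry | None = None) -> float:
    """Horizontal pixel coordinate at a signed eccentricity."""
    g = geometry or ScreenGeometry()
    cx, _ = g.center_px
    return cx + np.sign(angle_deg) * degrees_to_pixels(abs(angle_deg), g)
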