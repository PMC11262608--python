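"""Screen geometry: conversions between pixels and degrees of visual angle.

Eccentricity is measured as ``atan(planar offset / viewing distance)`` from
the gaze ray through the screen center (flat-screen approximation).  Pixels
are assumed square, with the centimetre-per-pixel scale derived from the
horizontal screen dimension.  The coordinate origin is the top-left corner
of the display with y increasing downward, so an upward target has a
*smaller* y coordinate than the screen center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "STUDY_DISPLAY",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "angular_distance_deg",
]

_CM_PER_INCH = 2.54


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and logical description of the stimulus display.

    Defaults describe a 23-inch 16:9 panel at 1920x1080 and 60 Hz viewed
    from 65 cm, the configuration all built-in conversions assume.
    """

    diagonal_inches: float = 23.0
    aspect_w: float = 16.0
    aspect_h: float = 9.0
    res_x: int = 1920
    res_y: int = 1080
    refresh_hz: float = 60.0
    viewing_distance_cm: float = 65.0

    def __post_init__(self) -> None:
        for name in (
            "diagonal_inches",
            "aspect_w",
            "aspect_h",
            "res_x",
            "res_y",
            "refresh_hz",
            "viewing_distance_cm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive")
        # square pixels: the stated aspect ratio must match the resolution
        if abs(self.res_x / self.res_y - self.aspect_w / self.aspect_h) > 0.01 * (
            self.aspect_w / self.aspect_h
        ):
            raise ValueError(
                "aspect ratio inconsistent with resolution (non-square pixels?)"
            )

    @property
    def width_cm(self) -> float:
        diag_cm = self.diagonal_inches * _CM_PER_INCH
        return diag_cm * self.aspect_w / math.hypot(self.aspect_w, self.aspect_h)

    @property
    def height_cm(self) -> float:
        diag_cm = self.diagonal_inches * _CM_PER_INCH
        return diag_cm * self.aspect_h / math.hypot(self.aspect_w, self.aspect_h)

    @property
    def cm_per_px(self) -> float:
        return self.width_cm / self.res_x

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.res_x / 2.0, self.res_y / 2.0)


#: The display used throughout unless another geometry is supplied.
STUDY_DISPLAY = ScreenGeometry()


def pixels_to_degrees(offset_px, geometry: ScreenGeometry = STUDY_DISPLAY):
    """Convert a radial pixel distance from screen center to visual angle.

    Parameters
    ----------
    offset_px : float or array_like
        Radial distance from the screen center, in pixels (>= 0).
    geometry : ScreenGeometry
        Display description supplying the pixel pitch and viewing distance.

    Returns
    -------
    float or ndarray
        Visual angle in degrees; strictly increasing and concave in
        ``offset_px``.
    """
    offset = np.asarray(offset_px, dtype=float)
    if np.any(offset < 0):
        raise ValueError("offset_px must be non-negative")
    angle = np.degrees(
        np.arctan(offset * geometry.cm_per_px / geometry.viewing_distance_cm)
    )
    return angle if angle.ndim else float(angle)


def degrees_to_pixels(angle_deg, geometry: ScreenGeometry = STUDY_DISPLAY):
    """Inverse of :func:`pixels_to_degrees`; angles must lie in [0, 90)."""
    angle = np.asarray(angle_deg, dtype=float)
    if np.any(angle < 0) or np.any(angle >= 90.0):
        raise ValueError("angle_deg must lie in [0, 90)")
    px = (
        np.tan(np.radians(angle))
        * geometry.viewing_distance_cm
        / geometry.cm_per_px
    )
    return px if px.ndim else float(px)


def angular_distance_deg(x1, y1, x2, y2, geometry: ScreenGeometry = STUDY_DISPLAY):
    """Angle in degrees between the gaze rays through two on-screen points.

    Points are pixel coordinates (origin top-left).  The eye is placed on
    the normal through the screen center at the viewing distance; the angle
    between the two 3-D gaze vectors is returned.  Vectorized over inputs.
    """
    cx, cy = geometry.center_px
    s = geometry.cm_per_px
    d = geometry.viewing_distance_cm
    ax = (np.asarray(x1, dtype=float) - cx) * s
    ay = (np.asarray(y1, dtype=float) - cy) * s
    bx = (np.asarray(x2, dtype=float) - cx) * s
    by = (np.asarray(y2, dtype=float) - cy) * s
    dot = ax * bx + ay * by + d * d
    # cross product magnitude of (ax, ay, d) x (bx, by, d)
    cx_ = ay * d - d * by
    cy_ = d * bx - ax * d
    cz_ = ax * by - ay * bx
    cross = np.sqrt(cx_**2 + cy_**2 + cz_**2)
    ang = np.degrees(np.arctan2(cross, dot))
    return ang if np.ndim(ang) else float(ang)
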