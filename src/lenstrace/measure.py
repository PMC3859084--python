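"""Optometric measurements from extracted lens contours.

The centering parameters a lens prescription needs, in the DIN "boxing
system" convention: the *boxing size* is the width and height of a lens's
bounding box, the *bridge* is the horizontal gap between the two rims, and
the *fitting height* is the vertical distance from the lens bottom to the
pupil.  All values are in pixels; supplying a mm-per-pixel scale (from a
calibrated capture device) converts them to millimetres.

No dedicated pupil detector is included: the pupil position defaults to
the detected eye center and can be overridden with supplied coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LenstraceError


class MeasurementError(LenstraceError):
    """Geometrically implausible extraction (overlapping rims, ...)."""


def boxing_size(contour: np.ndarray) -> tuple[float, float]:
    """Boxing (width, height) of one lens: extents of the contour bounding box."""
    pts = np.asarray(contour, float)
    w, h = pts.max(axis=0) - pts.min(axis=0)
    return float(w), float(h)


def bridge(left: np.ndarray, right: np.ndarray) -> float:
    """Horizontal gap between the left and right rims, pixels."""
    gap = float(np.asarray(right, float)[:, 0].min() - np.asarray(left, float)[:, 0].max())
    if gap < 0:
        raise MeasurementError(f"rims overlap horizontally by {-gap:.1f} px")
    return gap


def fitting_height(contour: np.ndarray, pupil) -> float:
    """Vertical distance from the lens bottom to the pupil, pixels.

    Image y grows downward, so the lens bottom is the maximal y.
    """
    pts = np.asarray(contour, float)
    py = float(pupil[1])
    if not pts[:, 1].min() <= py:
        raise MeasurementError("pupil lies above the lens")
    fh = float(pts[:, 1].max() - py)
    if fh < 0:
        raise MeasurementError("pupil lies below the lens bottom")
    return fh


@dataclass(frozen=True)
class Measurements:
    """Bridge, per-lens boxing sizes and fitting heights (pixels, optional mm)."""

    bridge: float
    boxing_left: tuple[float, float]
    boxing_right: tuple[float, float]
    fitting_left: float
    fitting_right: float
    scale_mm_per_px: float | None = None

    def in_mm(self, value: float) -> float | None:
        return None if self.scale_mm_per_px is None else value * self.scale_mm_per_px

    def to_dict(self) -> dict:
        d = {
            "bridge_px": self.bridge,
            "boxing_left_px": list(self.boxing_left),
            "boxing_right_px": list(self.boxing_right),
            "fitting_left_px": self.fitting_left,
            "fitting_right_px": self.fitting_right,
        }
        if self.scale_mm_per_px is not None:
            s = self.scale_mm_per_px
            d.update({
                "scale_mm_per_px": s,
                "bridge_mm": self.bridge * s,
                "boxing_left_mm": [v * s for v in self.boxing_left],
                "boxing_right_mm": [v * s for v in self.boxing_right],
                "fitting_left_mm": self.fitting_left * s,
                "fitting_right_mm": self.fitting_right * s,
            })
        return d


def measure_lenses(left: np.ndarray, right: np.ndarray, left_pupil, right_pupil,
                   scale_mm_per_px: float | None = None) -> Measurements:
    """All centering measurements for an extracted rim pair."""
    if scale_mm_per_px is not None and scale_mm_per_px <= 0:
        raise MeasurementError("scale_mm_per_px must be positive")
    return Measurements(
        bridge=bridge(left, right),
        boxing_left=boxing_size(left),
        boxing_right=boxing_size(right),
        fitting_left=fitting_height(left, left_pupil),
        fitting_right=fitting_height(right, right_pupil),
        scale_mm_per_px=scale_mm_per_px,
    )
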