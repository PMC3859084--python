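"""Hypothesis scoring against the distance field, and geometric validation.

A hypothesized rim contour is scored by rasterizing its boundary onto the
Euclidean distance transform of the edge map and averaging the
distance-transform values under the boundary pixels — a chamfer matching
score in pixels of mean edge distance.  Zero means the contour lies exactly
on edges; *lower is better*, and every "best" selection in the search and
refinement stages minimizes this score.

Before scoring, hypotheses must pass a set of facial-plausibility checks:
the rims must enclose the eyes, sit close to and be larger than them, stay
inside the search ROI, and respect the neoclassical facial-fifths canon
(the face divides into five equal vertical bands, the intercanthal gap
being the middle fifth; the left lens must live in bands 1-3, the right in
bands 3-5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContourError
from .geometry import Rect, point_in_polygon
from .preprocess import EyeRegion, SearchROI

#: clause (b) threshold: lens centroid must be within this many IPDs of its eye
CENTROID_TOL_IPD = 0.25


@dataclass(frozen=True)
class MatchScore:
    """Per-rim and combined mean edge distance (pixels; lower is better)."""

    left: float
    right: float

    @property
    def combined(self) -> float:
        return (self.left + self.right) / 2.0


def rasterize_boundary(contour: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """8-connected pixel set under a closed polyline, as (rows, cols).

    Consecutive contour points are joined by digital segments; duplicate
    pixels are counted once.  Pixels falling outside ``shape`` are clamped
    to the border (they then read the border distance value), keeping the
    pixel count stable for contours grazing the ROI edge.
    """
    pts = np.asarray(contour, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ContourError("contour must be an (N, 2) array with N >= 3")
    h, w = shape
    inside = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
    if not inside.any():
        raise ContourError("contour lies entirely outside the field")
    p0 = pts
    p1 = np.roll(pts, -1, axis=0)
    span = np.abs(p1 - p0)
    n_steps = int(np.ceil(span.max())) + 1
    t = np.linspace(0.0, 1.0, n_steps)
    samples = p0[:, None, :] + t[None, :, None] * (p1 - p0)[:, None, :]
    cols = np.clip(np.rint(samples[..., 0]).astype(int).ravel(), 0, w - 1)
    rows = np.clip(np.rint(samples[..., 1]).astype(int).ravel(), 0, h - 1)
    flat = np.unique(rows.astype(np.int64) * w + cols)
    return flat // w, flat % w


def rim_score(contour: np.ndarray, df: np.ndarray) -> float:
    """Mean distance-transform value under the rasterized rim boundary."""
    rows, cols = rasterize_boundary(contour, df.shape)
    return float(df[rows, cols].mean())


def hypothesis_score(left: np.ndarray, right: np.ndarray, df: np.ndarray) -> MatchScore:
    """Combined score of a rim pair: the mean of the two per-rim scores."""
    return MatchScore(left=rim_score(left, df), right=rim_score(right, df))


@dataclass(frozen=True)
class FaceFifths:
    """Five equal-width vertical face bands; boundaries[i..i+1] is band i+1."""

    boundaries: np.ndarray  # 6 ascending x-coordinates

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, float)
        object.__setattr__(self, "boundaries", b)
        if b.shape != (6,) or not np.all(np.diff(b) > 0):
            raise ValueError("fifths need 6 strictly ascending boundaries")

    def band(self, i: int) -> tuple[float, float]:
        """1-based band index -> (x_start, x_end)."""
        return float(self.boundaries[i - 1]), float(self.boundaries[i])

    @property
    def width(self) -> float:
        return float(self.boundaries[1] - self.boundaries[0])


def face_fifths(eyes: EyeRegion) -> FaceFifths:
    """Facial-fifths bands anchored on the intercanthal gap.

    The middle (third) band spans the gap between the inner edges of the
    two eye rectangles; the remaining four bands extend outward with the
    same width.
    """
    x0 = eyes.left_rect.x1
    x1 = eyes.right_rect.x
    g = x1 - x0
    if g <= 0:
        raise ValueError("eye rectangles overlap; no intercanthal gap")
    return FaceFifths(np.array([x0 - 2 * g, x0 - g, x0, x1, x1 + g, x1 + 2 * g]))


def validate_hypothesis(left_contour: np.ndarray, right_contour: np.ndarray,
                        eyes: EyeRegion, roi: SearchROI, fifths: FaceFifths,
                        centroid_tol_ipd: float = CENTROID_TOL_IPD) -> tuple[bool, str]:
    """Check a rim pair against the facial-plausibility constraints.

    Returns ``(True, "ok")`` or ``(False, reason)`` with reason one of
    ``fifths`` (lens sides outside its allowed bands), ``size`` (lens
    bounding box not strictly larger than the eye rectangle), ``enclosure``
    (eye center not strictly inside the rim), ``centroid`` (lens centroid
    farther than ``centroid_tol_ipd``*IPD from its eye center) or ``roi``
    (contour leaves the search rectangle).
    """
    left_bb = Rect.bounding(left_contour)
    right_bb = Rect.bounding(right_contour)

    lo, hi = fifths.band(1)[0], fifths.band(3)[1]
    if not (lo <= left_bb.x and left_bb.x1 <= hi):
        return False, "fifths"
    lo, hi = fifths.band(3)[0], fifths.band(5)[1]
    if not (lo <= right_bb.x and right_bb.x1 <= hi):
        return False, "fifths"

    for bb, er in ((left_bb, eyes.left_rect), (right_bb, eyes.right_rect)):
        if not (bb.w > er.w and bb.h > er.h):
            return False, "size"

    for contour, center in ((left_contour, eyes.left_center),
                            (right_contour, eyes.right_center)):
        if not point_in_polygon(center, np.asarray(contour, float)):
            return False, "enclosure"

    tol = centroid_tol_ipd * eyes.ipd
    for contour, center in ((left_contour, eyes.left_center),
                            (right_contour, eyes.right_center)):
        centroid = np.asarray(contour, float).mean(axis=0)
        if np.linalg.norm(centroid - center) > tol:
            return False, "centroid"

    for bb in (left_bb, right_bb):
        if not roi.rect.contains_rect(bb):
            return False, "roi"

    return True, "ok"
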