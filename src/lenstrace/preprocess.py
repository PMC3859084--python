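"""Eye localization, search ROI, edge map and distance transform.

The lens search needs three things from the raw image: the two eye centers
(and from them the interpupillary distance, IPD — the model's single size
reference), a search rectangle around the eyes, and the Euclidean distance
transform of the Canny edge map restricted to that rectangle.  Hypothesized
rim contours are later scored by the mean distance-transform value under
their boundary, a chamfer-style matching score.

Eye localization is pluggable: any detector that returns candidate eye
rectangles can drive :func:`detect_eyes` (a cascade classifier, the
dark-blob template detector used for synthetic scenes, ...), or the caller
can supply eye centers directly via :func:`eyes_from_centers`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import feature, filters, measure

from .errors import EmptyEdgeMapError, EyeDetectionError, TiltError
from .geometry import Rect


def load_image(path) -> np.ndarray:
    """Read PNG/JPEG/TIFF/PGM as an 8-bit grayscale array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


@dataclass(frozen=True)
class EyeRegion:
    """Located eyes: centers, surrounding rectangles and the IPD."""

    left_center: np.ndarray
    right_center: np.ndarray
    left_rect: Rect
    right_rect: Rect

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_center", np.asarray(self.left_center, float))
        object.__setattr__(self, "right_center", np.asarray(self.right_center, float))
        if self.left_center[0] >= self.right_center[0]:
            raise EyeDetectionError("left eye center must lie left of the right one")

    @property
    def ipd(self) -> float:
        return interpupillary_distance(self)


@dataclass(frozen=True)
class SearchROI:
    """Eyeglasses search rectangle with its expansion factor delta."""

    rect: Rect
    delta: float


def interpupillary_distance(eyes: EyeRegion) -> float:
    """Euclidean distance between the two eye centers, pixels."""
    return float(np.linalg.norm(eyes.right_center - eyes.left_center))


def _tilt_deg(left_center, right_center) -> float:
    d = np.asarray(right_center, float) - np.asarray(left_center, float)
    return abs(np.degrees(np.arctan2(d[1], d[0])))


def detect_eyes(image: np.ndarray, detector, max_tilt_deg: float = 10.0) -> EyeRegion:
    """Group single-eye candidate rectangles into a left/right eye pair.

    ``detector(image)`` must return candidate rectangles (:class:`Rect` or
    (x, y, w, h) tuples).  The grouping pipeline: (1) discard candidates
    without a counterpart on the opposite side of the overall candidate
    centroid at similar height (vertical offset within a quarter of the
    taller candidate or a ~17 degree cone over their horizontal
    separation); (2) split survivors into left/right groups about the overall
    center; (3) merge overlapping zones into their enclosing rectangle;
    (4) each eye center is the centroid of its side's merged zones, and the
    eye rectangle size is the midpoint between the smallest and the mean
    merged-zone size.  Raises :class:`TiltError` if the inter-eye slope
    exceeds ``max_tilt_deg`` (frontal, near-level head pose is assumed).
    """
    cands = [r if isinstance(r, Rect) else Rect(*r) for r in detector(image)]
    if len(cands) < 2:
        raise EyeDetectionError(f"need at least two eye candidates, got {len(cands)}")
    centers = np.array([c.center for c in cands])
    mid_x = centers[:, 0].mean()

    def _paired(i: int) -> bool:
        for j in range(len(cands)):
            if j == i:
                continue
            opposite = (centers[i, 0] - mid_x) * (centers[j, 0] - mid_x) < 0
            # similar height: within a quarter of the taller candidate, or
            # within a ~17 degree cone over their horizontal separation so
            # that moderately tilted heads reach the explicit tilt check
            # below instead of silently losing their pair
            tol = max(0.25 * max(cands[i].h, cands[j].h),
                      0.30 * abs(centers[i, 0] - centers[j, 0]))
            similar = abs(centers[i, 1] - centers[j, 1]) <= tol
            if opposite and similar:
                return True
        return False

    keep = [i for i in range(len(cands)) if _paired(i)]
    if not keep:
        raise EyeDetectionError("no left/right eye candidate pair found")
    left = [cands[i] for i in keep if centers[i, 0] < mid_x]
    right = [cands[i] for i in keep if centers[i, 0] >= mid_x]
    if not left or not right:
        raise EyeDetectionError("candidates collapse onto one side")

    def _merge_overlapping(zones: list[Rect]) -> list[Rect]:
        zones = list(zones)
        merged = True
        while merged:
            merged = False
            for i in range(len(zones)):
                for j in range(i + 1, len(zones)):
                    if zones[i].intersects(zones[j]):
                        zones[i] = zones[i].union(zones[j])
                        del zones[j]
                        merged = True
                        break
                if merged:
                    break
        return zones

    left = _merge_overlapping(left)
    right = _merge_overlapping(right)
    left_center = np.mean([z.center for z in left], axis=0)
    right_center = np.mean([z.center for z in right], axis=0)

    tilt = _tilt_deg(left_center, right_center)
    if tilt > max_tilt_deg:
        raise TiltError(f"inter-eye slope {tilt:.1f} deg exceeds {max_tilt_deg} deg")

    # eye area: midpoint between the smallest and the mean merged-zone size
    all_zones = left + right
    widths = np.array([z.w for z in all_zones])
    heights = np.array([z.h for z in all_zones])
    w = (widths.min() + widths.mean()) / 2.0
    h = (heights.min() + heights.mean()) / 2.0
    return EyeRegion(
        left_center=left_center,
        right_center=right_center,
        left_rect=Rect.from_center(left_center, w, h),
        right_rect=Rect.from_center(right_center, w, h),
    )


def eyes_from_centers(left_center, right_center, rect_width_ipd: float = 0.18,
                      rect_height_ipd: float = 0.11,
                      max_tilt_deg: float = 10.0) -> EyeRegion:
    """Build an :class:`EyeRegion` from externally supplied eye centers.

    Eye rectangles are synthesized at an anthropometrically plausible size
    relative to the IPD (defaults: 0.18 x 0.11 IPD).  Centers may be given
    in either order; they are sorted left-to-right.
    """
    a = np.asarray(left_center, float)
    b = np.asarray(right_center, float)
    if a[0] > b[0]:
        a, b = b, a
    tilt = _tilt_deg(a, b)
    if tilt > max_tilt_deg:
        raise TiltError(f"inter-eye slope {tilt:.1f} deg exceeds {max_tilt_deg} deg")
    ipd = float(np.linalg.norm(b - a))
    if ipd <= 0:
        raise EyeDetectionError("coincident eye centers")
    w = rect_width_ipd * ipd
    h = rect_height_ipd * ipd
    return EyeRegion(a, b, Rect.from_center(a, w, h), Rect.from_center(b, w, h))


def template_eye_candidates(image: np.ndarray, threshold: int = 60,
                            min_area: int = 50) -> list[Rect]:
    """Dark-blob eye candidate detector for synthetic scenes.

    Thresholds for near-black blobs (rendered pupils) and returns their
    bounding rectangles.  A stand-in for a trained eye detector, usable only
    on imagery where the pupils are the darkest compact structures.
    """
    mask = np.asarray(image) < threshold
    labels = measure.label(mask)
    out = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        out.append(Rect(float(c0), float(r0), float(c1 - c0), float(r1 - r0)))
    return out


def cascade_eye_candidates(image: np.ndarray, cascade_path) -> list[Rect]:
    """Candidate rectangles from a user-supplied skimage cascade classifier."""
    cascade = feature.Cascade(open(cascade_path, "rb").read())
    hits = cascade.detect_multi_scale(
        img=np.asarray(image), scale_factor=1.2, step_ratio=1.3,
        min_size=(12, 12), max_size=(image.shape[0] // 2, image.shape[1] // 2))
    return [Rect(float(h["c"]), float(h["r"]), float(h["width"]), float(h["height"]))
            for h in hits]


def eyeglass_roi(eyes: EyeRegion, delta: float = 1.5,
                 image_shape: tuple[int, int] | None = None) -> SearchROI:
    """Eyeglasses search rectangle around the eyes.

    Centered on the inter-eye midpoint; horizontal half-extent
    IPD*(1 + delta)/2, vertical half-extent delta*IPD/2 — wide enough at
    delta = 1.5 to enclose large frames while keeping the hypothesis space
    bounded.  Clipped to the image bounds when ``image_shape`` is given;
    raises if clipping cuts into either eye rectangle.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    ipd = eyes.ipd
    if ipd <= 0:
        raise EyeDetectionError("degenerate interpupillary distance")
    mid = (eyes.left_center + eyes.right_center) / 2.0
    rect = Rect.from_center(mid, (1.0 + delta) * ipd, delta * ipd)
    if image_shape is not None:
        h, w = image_shape[:2]
        rect = rect.clip_to(float(w), float(h))
        for er in (eyes.left_rect, eyes.right_rect):
            if not rect.contains_rect(er):
                raise EyeDetectionError("clipped ROI no longer contains the eye rects")
    return SearchROI(rect=rect, delta=delta)


def edge_map(image: np.ndarray, low_threshold: float | None = None,
             high_threshold: float | None = None, sigma: float = 1.4,
             roi: SearchROI | None = None) -> np.ndarray:
    """Canny edge map, optionally restricted to the search ROI.

    Thresholds act on the gradient magnitude of the [0, 1]-scaled image.
    When not given, the high threshold is derived by Otsu's method on the
    non-negligible gradient magnitudes inside the ROI and low = high / 2 —
    an adaptive default that separates the strong rim/feature edges from
    smooth shading.
    """
    img = np.asarray(image, dtype=float) / 255.0
    if low_threshold is not None and high_threshold is not None:
        if not 0 <= low_threshold < high_threshold:
            raise ValueError("thresholds require 0 <= low < high")
    if high_threshold is None:
        smoothed = ndimage.gaussian_filter(img, sigma)
        grad = np.hypot(ndimage.sobel(smoothed, axis=0), ndimage.sobel(smoothed, axis=1))
        if roi is not None:
            grad = grad[_roi_slices(roi, img.shape)]
        strong = grad[grad > 1e-4]
        high_threshold = float(filters.threshold_otsu(strong)) if strong.size else 0.1
    if low_threshold is None:
        low_threshold = high_threshold / 2.0
    edges = feature.canny(img, sigma=sigma, low_threshold=low_threshold,
                          high_threshold=high_threshold)
    if roi is not None:
        mask = np.zeros_like(edges)
        sl = _roi_slices(roi, edges.shape)
        mask[sl] = True
        edges &= mask
    return edges


def _roi_slices(roi: SearchROI, shape) -> tuple[slice, slice]:
    r = roi.rect.clip_to(float(shape[1]), float(shape[0]))
    return (slice(int(np.floor(r.y)), int(np.ceil(r.y1))),
            slice(int(np.floor(r.x)), int(np.ceil(r.x1))))


def distance_field(edges: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest edge pixel, per pixel."""
    edges = np.asarray(edges, bool)
    if not edges.any():
        raise EmptyEdgeMapError("edge map has no edge pixels")
    return ndimage.distance_transform_edt(~edges)
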