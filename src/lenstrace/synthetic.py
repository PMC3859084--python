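"""Seeded synthetic facial scenes with known lens contours.

Real optometric test imagery (frontal faces behind a measuring device) is
not redistributable, so the test-data supply is synthetic: a flat-background
face region with two dark pupil blobs, a mirror-symmetric pair of lens
regions rendered from the same morphed-descriptor shape model the search
uses, and optional clutter — eyebrow arcs, a nose line, specular blobs, a
decoy closed contour away from the eyes.  The generator returns the exact
rendered contours as ground truth, which makes end-to-end parameter
recovery measurable via the area-overlap criterion.

Rendering choices (see docs/methods.md): each lens is a filled tinted
region, so Canny recovers a single clean edge chain lying on the truth
boundary; rim *gaps* are local heavy-blur patches along boundary arcs,
which removes the edge response there the way low-contrast or reflective
rim segments do in real images.

What this emulates — and what it does not: partial rim contours, eyebrow
clutter, illumination noise, left-right symmetry.  It does not emulate
skin texture, hair, shadows, rimless frames or perspective distortion, so
passing recovery tests here demonstrates the search machinery, not
photographic robustness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import draw

from . import fourier_shape as fs
from .errors import ContourError, LenstraceError
from .geometry import Rect
from .matching import validate_hypothesis, face_fifths
from .preprocess import eyes_from_centers, eyeglass_roi
from .search import LensHypothesis, build_contours
from .shape_db import ShapeClass, ShapeDatabase

BG = 200          # background intensity
LENS_FILL = 150   # lens interior tint
PUPIL = 30        # pupil blob intensity
EYEBROW = 90      # eyebrow stroke intensity (dark enough for strong edges,
                  # above the template detector's pupil threshold)
NOSE = 120
DECOY = 90


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic scene."""

    width: int = 800
    height: int = 600
    eye_left: tuple[float, float] = (300.0, 280.0)
    eye_right: tuple[float, float] = (500.0, 280.0)
    cls: ShapeClass = ShapeClass.ELLIPTIC
    s1_id: str = "ellip_00"
    s2_id: str = "ellip_01"
    beta: float = 0.5
    size: float = 76.0                       # first-harmonic radius, pixels
    centroid_left: tuple[float, float] = (300.0, 280.0)
    right_cx: float = 500.0
    gap_fraction: float = 0.0                # fraction of each rim erased
    eyebrows: bool = False
    nose: bool = False
    specular: bool = False
    decoy: bool = False
    noise_sigma: float = 3.0                 # Gaussian intensity noise
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cls"] = self.cls.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["cls"] = ShapeClass(d["cls"])
        for key in ("eye_left", "eye_right", "centroid_left"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Exact rendered contours and scene geometry."""

    left_contour: np.ndarray
    right_contour: np.ndarray
    eye_left: np.ndarray
    eye_right: np.ndarray
    ipd: float
    cls: ShapeClass
    decoy_contour: np.ndarray | None = None


def _truth_contours(spec: SceneSpec, db: ShapeDatabase) -> tuple[np.ndarray, np.ndarray]:
    lens = LensHypothesis(cls=spec.cls, centroid=spec.centroid_left, size=spec.size,
                          s1_id=spec.s1_id, s2_id=spec.s2_id, beta=spec.beta)
    return build_contours(db, lens, spec.right_cx)


def _fill_polygon(canvas: np.ndarray, contour: np.ndarray, value: float) -> None:
    rr, cc = draw.polygon(contour[:, 1], contour[:, 0], shape=canvas.shape)
    canvas[rr, cc] = value


def _stroke(canvas: np.ndarray, points: np.ndarray, value: float, radius: int) -> None:
    for x, y in points:
        rr, cc = draw.disk((y, x), radius, shape=canvas.shape)
        canvas[rr, cc] = value


def _dense_boundary(contour: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample a closed contour at roughly ``step``-pixel arc spacing."""
    per = np.linalg.norm(np.diff(np.vstack([contour, contour[:1]]), axis=0), axis=1).sum()
    n = max(16, int(per / step))
    return fs.resample_contour(contour, n)


def _gap_mask(shape, contour: np.ndarray, gap_fraction: float,
              rng: np.random.Generator, radius: int = 5) -> np.ndarray:
    """Disk mask covering 2-3 random boundary arcs totaling gap_fraction."""
    mask = np.zeros(shape, bool)
    dense = _dense_boundary(contour, step=1.0)
    m = len(dense)
    n_arcs = int(rng.integers(2, 4))
    weights = rng.dirichlet(np.ones(n_arcs))
    starts = rng.integers(0, m, n_arcs)
    for w, s in zip(weights, starts):
        length = int(round(w * gap_fraction * m))
        idx = (np.arange(s, s + length)) % m
        for x, y in dense[idx]:
            rr, cc = draw.disk((y, x), radius, shape=shape)
            mask[rr, cc] = True
    return mask


def _decoy_contour(spec: SceneSpec) -> np.ndarray:
    """A closed superellipse well below the eye line (inside the ROI)."""
    mid_x = (spec.eye_left[0] + spec.eye_right[0]) / 2.0
    ipd = float(np.hypot(spec.eye_right[0] - spec.eye_left[0],
                         spec.eye_right[1] - spec.eye_left[1]))
    cy = spec.eye_left[1] + 0.55 * ipd
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    a, b = 0.16 * ipd, 0.12 * ipd
    x = mid_x + a * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** 0.9
    y = cy + b * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** 0.9
    return np.column_stack([x, y])


def generate_scene(spec: SceneSpec, db: ShapeDatabase,
                   rng: np.random.Generator | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene and return it with its exact ground truth.

    Deterministic: the same spec (including its seed) yields a bit-identical
    image.  Raises if the lens contours leave the image.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    left, right = _truth_contours(spec, db)
    for c in (left, right):
        if (c[:, 0].min() < 0 or c[:, 1].min() < 0
                or c[:, 0].max() >= spec.width or c[:, 1].max() >= spec.height):
            raise LenstraceError("lens contour leaves the image; inconsistent spec")

    canvas = np.full((spec.height, spec.width), float(BG))
    _fill_polygon(canvas, left, LENS_FILL)
    _fill_polygon(canvas, right, LENS_FILL)

    ipd = float(np.hypot(spec.eye_right[0] - spec.eye_left[0],
                         spec.eye_right[1] - spec.eye_left[1]))
    for ex, ey in (spec.eye_left, spec.eye_right):
        rr, cc = draw.ellipse(ey, ex, 0.055 * ipd, 0.09 * ipd, shape=canvas.shape)
        canvas[rr, cc] = PUPIL

    if spec.eyebrows:
        for ex, ey in (spec.eye_left, spec.eye_right):
            t = np.linspace(-1.0, 1.0, 60)
            bx = ex + 0.17 * ipd * t
            by = ey - 0.33 * ipd + 0.06 * ipd * t ** 2
            _stroke(canvas, np.column_stack([bx, by]), EYEBROW, 2)
    if spec.nose:
        mid_x = (spec.eye_left[0] + spec.eye_right[0]) / 2.0
        ny = np.linspace(spec.eye_left[1] - 0.05 * ipd, spec.eye_left[1] + 0.28 * ipd, 60)
        _stroke(canvas, np.column_stack([np.full_like(ny, mid_x), ny]), NOSE, 1)
    if spec.specular:
        for contour in (left, right):
            cx, cy = contour.mean(axis=0)
            rr, cc = draw.disk((cy - 0.35 * (cy - contour[:, 1].min()), cx + 0.02 * ipd),
                               0.035 * ipd, shape=canvas.shape)
            canvas[rr, cc] = 255

    decoy = None
    if spec.decoy:
        decoy = _decoy_contour(spec)
        _fill_polygon(canvas, decoy, DECOY)

    if spec.gap_fraction > 0:
        blurred = ndimage.gaussian_filter(canvas, 7.0)
        mask = (_gap_mask(canvas.shape, left, spec.gap_fraction, rng)
                | _gap_mask(canvas.shape, right, spec.gap_fraction, rng))
        # saturated feathered blend: alpha must reach 1 over the gap arc so
        # the rim step is fully replaced by its blur (no residual edge), and
        # the ramp must be gradual — a hard mask edge would itself create a
        # spurious intensity step (and hence phantom Canny edges)
        alpha = ndimage.gaussian_filter(
            ndimage.binary_dilation(mask, iterations=3).astype(float), 3.0)
        canvas = alpha * blurred + (1.0 - alpha) * canvas

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)

    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    truth = GroundTruth(left_contour=left, right_contour=right,
                        eye_left=np.asarray(spec.eye_left, float),
                        eye_right=np.asarray(spec.eye_right, float),
                        ipd=ipd, cls=spec.cls, decoy_contour=decoy)
    return image, truth


def _interior_mask_pair(detected: np.ndarray, truth: np.ndarray):
    """Rasterized interiors of both contours on a shared pixel-center grid."""
    det = Polygon(np.asarray(detected, float))
    tru = Polygon(np.asarray(truth, float))
    for name, poly in (("detected", det), ("truth", tru)):
        if poly.area <= 0 or not poly.is_valid:
            raise ContourError(f"{name} contour is degenerate or self-intersecting")
    x0 = int(np.floor(min(det.bounds[0], tru.bounds[0]))) - 1
    y0 = int(np.floor(min(det.bounds[1], tru.bounds[1]))) - 1
    x1 = int(np.ceil(max(det.bounds[2], tru.bounds[2]))) + 1
    y1 = int(np.ceil(max(det.bounds[3], tru.bounds[3]))) + 1
    xx, yy = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
    m_det = shapely.contains_xy(det, xx.ravel(), yy.ravel()).reshape(xx.shape)
    m_tru = shapely.contains_xy(tru, xx.ravel(), yy.ravel()).reshape(xx.shape)
    return m_det, m_tru


def overlap_fraction(detected: np.ndarray, truth: np.ndarray) -> float:
    """Area of (detected interior ∩ truth interior) over the truth area.

    The true-positive criterion: a detection is correct when this fraction
    reaches gamma (default 0.95).  The denominator is the *truth* area
    only, so the measure is deliberately asymmetric.
    """
    m_det, m_tru = _interior_mask_pair(detected, truth)
    n_truth = int(m_tru.sum())
    if n_truth == 0:
        raise ContourError("truth contour rasterizes to an empty interior")
    return float((m_det & m_tru).sum() / n_truth)


def contour_iou(detected: np.ndarray, truth: np.ndarray) -> float:
    """Intersection-over-union of the two interiors (symmetric diagnostic).

    Reported alongside :func:`overlap_fraction` because the truth-normalized
    overlap alone cannot penalize a grossly oversized detection.
    """
    m_det, m_tru = _interior_mask_pair(detected, truth)
    union = int((m_det | m_tru).sum())
    if union == 0:
        raise ContourError("both interiors are empty")
    return float((m_det & m_tru).sum() / union)


def random_scene_spec(rng: np.random.Generator, db: ShapeDatabase,
                      cls: ShapeClass | None = None, gap_fraction: float = 0.0,
                      eyebrows: bool = False, nose: bool = False,
                      specular: bool = False, decoy: bool = False,
                      noise_sigma: float = 3.0, width: int = 800,
                      height: int = 600) -> SceneSpec:
    """Draw a plausible scene spec: jittered eyes, class-consistent shape
    pair, realistic lens size and centroid offsets.

    Rejection-samples until the truth rim pair passes the pipeline's own
    geometric validation, stays inside the search ROI, and leaves a
    positive bridge gap between the rims.
    """
    if cls is None:
        cls = list(ShapeClass)[rng.integers(0, 3)]
    for _ in range(200):
        ey = 280.0 + rng.uniform(-10, 10)
        dy = rng.uniform(-4, 4)
        eye_left = (300.0 + rng.uniform(-10, 10), ey)
        eye_right = (500.0 + rng.uniform(-10, 10), ey + dy)
        ipd = float(np.hypot(eye_right[0] - eye_left[0], eye_right[1] - eye_left[1]))
        pool = db.by_class(cls)
        i, j = rng.integers(0, len(pool), 2)
        jit = 0.05 * ipd
        spec = SceneSpec(
            width=width, height=height, eye_left=eye_left, eye_right=eye_right,
            cls=cls, s1_id=pool[i].id, s2_id=pool[j].id,
            beta=float(rng.uniform(0, 1)),
            size=float(rng.uniform(0.35, 0.42) * ipd),
            centroid_left=(eye_left[0] + rng.uniform(-jit, jit),
                           eye_left[1] + rng.uniform(-jit, jit)),
            right_cx=float(eye_right[0] + rng.uniform(-jit, jit)),
            gap_fraction=gap_fraction, eyebrows=eyebrows, nose=nose,
            specular=specular, decoy=decoy, noise_sigma=noise_sigma,
            seed=int(rng.integers(2 ** 31)))
        try:
            left, right = _truth_contours(spec, db)
        except LenstraceError:
            continue
        if left[:, 0].max() >= right[:, 0].min() - 0.03 * ipd:
            continue  # rims touch: implausible frame
        eyes = eyes_from_centers(eye_left, eye_right)
        try:
            roi = eyeglass_roi(eyes, 1.5, image_shape=(height, width))
        except LenstraceError:
            continue
        ok, _ = validate_hypothesis(left, right, eyes, roi, face_fifths(eyes))
        if not ok:
            continue
        margin = 12.0
        box = Rect.bounding(np.vstack([left, right]))
        if box.x < margin or box.y < margin or box.x1 > width - margin or box.y1 > height - margin:
            continue
        return spec
    raise LenstraceError("could not draw a consistent scene spec")


def battery_specs(name: str, n_scenes: int, seed: int,
                  db: ShapeDatabase) -> list[SceneSpec]:
    """Standard fixture batteries: clean, cluttered (eyebrows + 20% gaps),
    decoy (extra off-eye closed contour).  Shape classes rotate round-robin
    so class identification is measurable."""
    kinds = {
        "clean": dict(),
        "cluttered": dict(eyebrows=True, nose=True, gap_fraction=0.2),
        "decoy": dict(decoy=True),
    }
    if name not in kinds:
        raise ValueError(f"unknown battery {name!r}; choose from {sorted(kinds)}")
    rng = np.random.default_rng(seed)
    classes = list(ShapeClass)
    return [random_scene_spec(rng, db, cls=classes[k % 3], **kinds[name])
            for k in range(n_scenes)]
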