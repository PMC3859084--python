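"""Monte Carlo hypothesis sampling and hypothesis clustering.

A lens hypothesis is the parameter vector

    v = [class, (x, y) centroid, size, {S1, S2} reference shapes, beta]

where the rim shape is the morph beta*S1 + (1-beta)*S2 of two same-class
database shapes and ``size`` is the first-harmonic radius in pixels.  The
right rim is derived, never sampled as a shape: it is the horizontal mirror
of the left rim, placed at an independently sampled x-offset from the right
eye at the same height as the left centroid (frames are assumed near
horizontal).

The search draws ``max_hypotheses`` hypotheses per class from uniform
distributions over IPD-relative bounds, keeps the ones passing geometric
validation, scores them on the distance field, and then groups them by an
agglomerative bounding-box-overlap clustering.  Selecting the best member
of the best-*mean*-score cluster (rather than the globally best hypothesis)
suppresses false positives: a lone well-scoring hypothesis on clutter drags
its cluster mean down, while the cluster around the true rims scores well
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import fourier_shape as fs
from .config import Config
from .errors import DatabaseError
from .geometry import Rect, intersection_area
from .matching import FaceFifths, MatchScore, rim_score
from .preprocess import EyeRegion, SearchROI
from .shape_db import ShapeClass, ShapeDatabase


@dataclass(frozen=True)
class LensHypothesis:
    """Parameters of a hypothesized left rim."""

    cls: ShapeClass
    centroid: tuple[float, float]
    size: float  # first-harmonic radius, pixels
    s1_id: str
    s2_id: str
    beta: float


@dataclass(frozen=True)
class GlassesHypothesis:
    """A left rim hypothesis plus its derived, mirrored right rim.

    ``right_cx`` is the right-rim centroid x; its y equals the left
    centroid's y.  Contours are the reconstructed 64-point boundaries in
    image coordinates; ``score`` is filled once matched against the
    distance field.  ``gen_index`` records generation order for
    deterministic tie-breaking.
    """

    left: LensHypothesis
    right_cx: float
    left_contour: np.ndarray
    right_contour: np.ndarray
    score: MatchScore | None = None
    gen_index: int = 0

    @property
    def right_centroid(self) -> np.ndarray:
        return np.array([self.right_cx, self.left.centroid[1]])

    @property
    def bbox(self) -> Rect:
        """Union of the two lens bounding boxes (the clustering feature)."""
        return Rect.bounding(self.left_contour).union(Rect.bounding(self.right_contour))


def build_contours(db: ShapeDatabase, lens: LensHypothesis, right_cx: float,
                   n_points: int = fs.DEFAULT_N_POINTS) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the left and mirrored right rim contours of a hypothesis.

    All transforms happen in descriptor space: morph the two normalized
    reference shapes, place at the left centroid and size, horizontally
    flip about the centroid, and translate the flipped set to the right
    centroid.
    """
    s1 = db.get(lens.s1_id).desc
    s2 = db.get(lens.s2_id).desc
    morphed = fs.morph_descriptors(s1, s2, lens.beta)
    placed = fs.place_descriptors(morphed, lens.centroid, lens.size)
    left = fs.descriptors_to_contour(placed, n_points)
    flipped = fs.hflip_descriptors(placed)
    right_desc = fs.translate_descriptors(flipped, (right_cx, lens.centroid[1]))
    right = fs.descriptors_to_contour(right_desc, n_points)
    return left, right


def sample_hypothesis(cls: ShapeClass, eyes: EyeRegion, db: ShapeDatabase,
                      cfg: Config, rng: np.random.Generator,
                      gen_index: int = 0) -> GlassesHypothesis:
    """Draw one hypothesis from the uniform proposal distributions.

    Left centroid uniform in a square box of half-width
    ``centroid_box_ipd``*IPD around the left eye center; right centroid x
    likewise around the right eye (mirrored independence), y tied to the
    left; size uniform in [size_min, size_max]*IPD; shape pair uniform
    within the class; beta uniform in [0, 1].
    """
    params = _sample_params(cls, eyes, db, cfg, rng, 1)
    return _build_batch(db, params, cfg, gen_index0=gen_index)[0]


def _sample_params(cls, eyes, db, cfg, rng, n):
    pool = db.by_class(cls)
    if not pool:
        raise DatabaseError(f"shape class {cls.value!r} is empty")
    ipd = eyes.ipd
    box = cfg.search.centroid_box_ipd * ipd
    cx = rng.uniform(eyes.left_center[0] - box, eyes.left_center[0] + box, n)
    cy = rng.uniform(eyes.left_center[1] - box, eyes.left_center[1] + box, n)
    size = rng.uniform(cfg.search.size_min_ipd * ipd, cfg.search.size_max_ipd * ipd, n)
    pair = rng.integers(0, len(pool), size=(n, 2))
    beta = rng.uniform(0.0, 1.0, n)
    rcx = rng.uniform(eyes.right_center[0] - box, eyes.right_center[0] + box, n)
    return {"cls": cls, "pool": pool, "cx": cx, "cy": cy, "size": size,
            "pair": pair, "beta": beta, "rcx": rcx}


def _build_batch(db, params, cfg, gen_index0=0):
    """Vectorized contour reconstruction for a batch of sampled parameters."""
    pool = params["pool"]
    n = len(params["beta"])
    n_pts = cfg.descriptors.n_points
    coeff_mat = np.stack([e.desc.coeffs for e in pool])  # (E, K)
    indices = pool[0].desc.indices
    npts_src = pool[0].desc.n_points
    i = np.arange(n_pts)
    phases = np.exp(2j * np.pi * np.outer(indices, i) / n_pts)  # (K, P)

    beta = params["beta"][:, None]
    morphed = beta * coeff_mat[params["pair"][:, 0]] + (1 - beta) * coeff_mat[params["pair"][:, 1]]
    scaled = morphed * (params["size"][:, None] * npts_src)
    z = (scaled @ phases) / npts_src  # centered shapes, (n, P)
    left = np.empty((n, n_pts, 2))
    left[..., 0] = z.real + params["cx"][:, None]
    left[..., 1] = z.imag + params["cy"][:, None]
    # horizontal mirror about the left centroid, re-centered on the right x
    right = np.empty_like(left)
    right[..., 0] = params["rcx"][:, None] - z.real
    right[..., 1] = left[..., 1]

    out = []
    for k in range(n):
        lens = LensHypothesis(
            cls=params["cls"], centroid=(float(params["cx"][k]), float(params["cy"][k])),
            size=float(params["size"][k]), s1_id=pool[params["pair"][k, 0]].id,
            s2_id=pool[params["pair"][k, 1]].id, beta=float(params["beta"][k]))
        out.append(GlassesHypothesis(left=lens, right_cx=float(params["rcx"][k]),
                                     left_contour=left[k], right_contour=right[k],
                                     gen_index=gen_index0 + k))
    return out


def _batch_valid_mask(left, right, eyes, roi, fifths, centroid_tol_ipd):
    """Vectorized validation of (n, P, 2) contour batches; mirrors
    :func:`lenstrace.matching.validate_hypothesis` clause for clause."""
    n = left.shape[0]
    ok = np.ones(n, bool)
    lmin, lmax = left.min(axis=1), left.max(axis=1)
    rmin, rmax = right.min(axis=1), right.max(axis=1)

    b = fifths.boundaries
    ok &= (lmin[:, 0] >= b[0]) & (lmax[:, 0] <= b[3])
    ok &= (rmin[:, 0] >= b[2]) & (rmax[:, 0] <= b[5])

    for mn, mx, er in ((lmin, lmax, eyes.left_rect), (rmin, rmax, eyes.right_rect)):
        ok &= (mx[:, 0] - mn[:, 0] > er.w) & (mx[:, 1] - mn[:, 1] > er.h)

    for contours, center in ((left, eyes.left_center), (right, eyes.right_center)):
        px = contours[..., 0]
        py = contours[..., 1]
        qx = np.roll(px, -1, axis=1)
        qy = np.roll(py, -1, axis=1)
        crosses = (py > center[1]) != (qy > center[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = px + (center[1] - py) * (qx - px) / (qy - py)
        inside = (np.count_nonzero(crosses & (center[0] < x_at), axis=1) % 2).astype(bool)
        ok &= inside

    tol = centroid_tol_ipd * eyes.ipd
    for contours, center in ((left, eyes.left_center), (right, eyes.right_center)):
        d = np.linalg.norm(contours.mean(axis=1) - np.asarray(center), axis=1)
        ok &= d <= tol

    r = roi.rect
    for mn, mx in ((lmin, lmax), (rmin, rmax)):
        ok &= (mn[:, 0] >= r.x) & (mn[:, 1] >= r.y) & (mx[:, 0] <= r.x1) & (mx[:, 1] <= r.y1)
    return ok


def monte_carlo_search(df: np.ndarray, eyes: EyeRegion, roi: SearchROI,
                       fifths: FaceFifths, db: ShapeDatabase, cls: ShapeClass,
                       cfg: Config, rng: np.random.Generator) -> list[GlassesHypothesis]:
    """Sample, validate and score ``max_hypotheses`` hypotheses of one class.

    Returns the valid hypotheses with their scores attached (possibly
    empty: no plausible fit of this class in the image).
    """
    n = cfg.search.max_hypotheses
    params = _sample_params(cls, eyes, db, cfg, rng, n)
    pool = params["pool"]
    hyps = _build_batch(db, params, cfg)
    left = np.stack([h.left_contour for h in hyps])
    right = np.stack([h.right_contour for h in hyps])
    ok = _batch_valid_mask(left, right, eyes, roi, fifths,
                           centroid_tol_ipd=0.25)
    out = []
    for k in np.nonzero(ok)[0]:
        h = hyps[k]
        score = MatchScore(left=rim_score(h.left_contour, df),
                           right=rim_score(h.right_contour, df))
        out.append(replace(h, score=score))
    return out


def rect_overlap_fraction(r1: Rect, r2: Rect) -> float:
    """Bounding-rectangle overlap: intersection area over the smaller area."""
    if r1.area <= 0 or r2.area <= 0:
        raise ValueError("zero-area rectangle")
    return intersection_area(r1, r2) / min(r1.area, r2.area)


@dataclass
class HypothesisCluster:
    """A group of positionally/size-wise similar hypotheses."""

    members: list[GlassesHypothesis]
    bbox: Rect

    @property
    def cluster_score(self) -> float:
        return float(np.mean([m.score.combined for m in self.members]))

    @property
    def best_member(self) -> GlassesHypothesis:
        # minimal combined score; ties broken by earliest generation index
        return min(self.members, key=lambda m: (m.score.combined, m.gen_index))


def cluster_hypotheses(hyps: list[GlassesHypothesis],
                       alpha: float = 0.90) -> list[HypothesisCluster]:
    """Agglomerative clustering by bounding-box overlap.

    Starting from singletons, repeatedly merge the pair of clusters with
    the highest mutual overlap fraction while that fraction is at least
    ``alpha``; a merged cluster's box is the enclosing rectangle.  The
    result is a partition of the input, deterministic given input order.
    """
    if not hyps:
        raise ValueError("cannot cluster an empty hypothesis list")
    boxes = [h.bbox for h in hyps]
    n = len(hyps)
    x0 = np.array([b.x for b in boxes])
    y0 = np.array([b.y for b in boxes])
    x1 = np.array([b.x1 for b in boxes])
    y1 = np.array([b.y1 for b in boxes])
    members: list[list[int] | None] = [[i] for i in range(n)]

    def _overlap_row(i):
        w = np.minimum(x1, x1[i]) - np.maximum(x0, x0[i])
        h = np.minimum(y1, y1[i]) - np.maximum(y0, y0[i])
        inter = np.clip(w, 0, None) * np.clip(h, 0, None)
        area = (x1 - x0) * (y1 - y0)
        return inter / np.minimum(area, area[i])

    ov = np.full((n, n), -1.0)
    for i in range(n):
        ov[i] = _overlap_row(i)
    np.fill_diagonal(ov, -1.0)

    while True:
        i, j = np.unravel_index(np.argmax(ov), ov.shape)
        if ov[i, j] < alpha:
            break
        i, j = min(i, j), max(i, j)
        members[i] = members[i] + members[j]  # type: ignore[operator]
        members[j] = None
        x0[i], y0[i] = min(x0[i], x0[j]), min(y0[i], y0[j])
        x1[i], y1[i] = max(x1[i], x1[j]), max(y1[i], y1[j])
        ov[j, :] = -1.0
        ov[:, j] = -1.0
        row = _overlap_row(i)
        alive = np.array([m is not None for m in members])
        row[~alive] = -1.0
        row[i] = -1.0
        ov[i, :] = row
        ov[:, i] = row

    out = []
    for i, m in enumerate(members):
        if m is None:
            continue
        out.append(HypothesisCluster(
            members=[hyps[k] for k in m],
            bbox=Rect(x0[i], y0[i], x1[i] - x0[i], y1[i] - y0[i])))
    return out


def select_best(clusters: list[HypothesisCluster]) -> GlassesHypothesis:
    """Best member of the best-mean-score cluster.

    Cluster-first selection implements the false-positive suppression: the
    chosen cluster is the one whose *members on average* match the edges
    best, and only then is its single best member returned.
    """
    if not clusters:
        raise ValueError("no clusters to select from")
    best_cluster = min(clusters,
                       key=lambda c: (c.cluster_score,
                                      min(m.gen_index for m in c.members)))
    return best_cluster.best_member
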