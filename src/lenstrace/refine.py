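"""Random-walk refinement and end-to-end lens extraction.

The Monte Carlo stage only brackets the rims; the random walk fine-tunes
them.  Each iteration perturbs exactly one dimension of the current
solution — left centroid, right centroid x, size, or morph factor beta —
by a Gaussian draw, re-validates and re-scores it, and keeps the move only
if the combined mean edge distance strictly decreases.  The score
trajectory is therefore non-increasing and the refined solution is never
worse than its start.

:func:`extract_lenses` runs the whole pipeline per shape class (sampling,
clustering, selection, refinement) and returns the class solution with the
lowest score, failing if no class yields a valid hypothesis or the best
mean edge distance exceeds the reject threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import Config
from .errors import ExtractionError, EyeDetectionError
from .matching import FaceFifths, MatchScore, face_fifths, rim_score, validate_hypothesis
from .preprocess import (
    EyeRegion,
    SearchROI,
    cascade_eye_candidates,
    detect_eyes,
    distance_field,
    edge_map,
    eyeglass_roi,
    eyes_from_centers,
    template_eye_candidates,
)
from .search import (
    GlassesHypothesis,
    LensHypothesis,
    build_contours,
    cluster_hypotheses,
    monte_carlo_search,
    select_best,
)
from .shape_db import ShapeClass, ShapeDatabase


@dataclass(frozen=True)
class ProposalModel:
    """Annealed per-dimension Gaussian proposal scales.

    ``sigma_*`` are the *initial* standard deviations; over the course of
    the walk each scale decays geometrically to ``anneal_floor`` times its
    initial value.  Early iterations therefore make coarse moves large
    enough to escape the compensated position/size offsets the Monte Carlo
    stage leaves behind, while late iterations polish at sub-pixel scale.
    A fixed scale provably does neither well: it is too large for the final
    polish and too small to cross the valley walls of the chamfer score.
    """

    sigma_position: float  # pixels, initial
    sigma_size: float      # pixels, initial
    sigma_beta: float      # unitless, initial
    anneal_floor: float = 0.05

    def scales_at(self, iteration: int, n_iterations: int) -> tuple[float, float, float]:
        """Proposal scales for one iteration of the geometric schedule."""
        if n_iterations <= 1:
            return self.sigma_position, self.sigma_size, self.sigma_beta
        decay = self.anneal_floor ** (iteration / (n_iterations - 1))
        return (self.sigma_position * decay, self.sigma_size * decay,
                self.sigma_beta * decay)

    @classmethod
    def from_config(cls, cfg: Config, ipd: float) -> "ProposalModel":
        return cls(sigma_position=cfg.refine.sigma_pos_ipd * ipd,
                   sigma_size=cfg.refine.sigma_size_ipd * ipd,
                   sigma_beta=cfg.refine.sigma_beta,
                   anneal_floor=cfg.refine.anneal_floor)


@dataclass(frozen=True)
class ExtractionResult:
    """Final extracted rim pair with per-class diagnostics."""

    left_contour: np.ndarray
    right_contour: np.ndarray
    hypothesis: GlassesHypothesis
    score: MatchScore
    class_scores: dict[str, float | None]
    eyes: EyeRegion
    roi: SearchROI


def _rebuild(db: ShapeDatabase, hyp: GlassesHypothesis, lens: LensHypothesis,
             right_cx: float, cfg: Config) -> GlassesHypothesis:
    left, right = build_contours(db, lens, right_cx, cfg.descriptors.n_points)
    return replace(hyp, left=lens, right_cx=right_cx,
                   left_contour=left, right_contour=right, score=None)


def random_walk_refine(x0: GlassesHypothesis, df: np.ndarray, eyes: EyeRegion,
                       roi: SearchROI, fifths: FaceFifths, pm: ProposalModel,
                       db: ShapeDatabase, cfg: Config, rng: np.random.Generator,
                       max_iterations: int | None = None) -> GlassesHypothesis:
    """Accept-if-better random walk around a scored hypothesis.

    Each of the ``max_iterations`` iterations sweeps once over the four
    dimensions — left centroid, right centroid x, size, morph factor beta
    — in randomized order, perturbing one dimension at a time by a
    Gaussian draw at that iteration's annealed scale and keeping the move
    only if the combined score strictly decreases.  Beta is clamped to
    [0, 1]; the reference shape pair is never re-drawn.  The returned
    hypothesis always scores at or below ``x0``.
    """
    if x0.score is None:
        raise ValueError("x0 must be scored before refinement")
    if max_iterations is None:
        max_iterations = cfg.refine.max_iterations
    current = x0
    dims = ("left_centroid", "right_centroid", "size", "beta")
    for iteration in range(max_iterations):
        sigma_pos, sigma_size, sigma_beta = pm.scales_at(iteration, max_iterations)
        for d in rng.permutation(len(dims)):
            dim = dims[d]
            lens = current.left
            right_cx = current.right_cx
            if dim == "left_centroid":
                dx, dy = rng.normal(0.0, sigma_pos, 2)
                lens = replace(lens, centroid=(lens.centroid[0] + dx, lens.centroid[1] + dy))
            elif dim == "right_centroid":
                right_cx = right_cx + rng.normal(0.0, sigma_pos)
            elif dim == "size":
                new_size = lens.size + rng.normal(0.0, sigma_size)
                if new_size <= 0:
                    continue
                lens = replace(lens, size=new_size)
            else:
                beta = float(np.clip(lens.beta + rng.normal(0.0, sigma_beta), 0.0, 1.0))
                lens = replace(lens, beta=beta)
            candidate = _rebuild(db, current, lens, right_cx, cfg)
            ok, _ = validate_hypothesis(candidate.left_contour, candidate.right_contour,
                                        eyes, roi, fifths)
            if not ok:
                continue
            score = MatchScore(left=rim_score(candidate.left_contour, df),
                               right=rim_score(candidate.right_contour, df))
            if score.combined < current.score.combined:
                current = replace(candidate, score=score)
    return current


def resolve_eyes(image: np.ndarray, cfg: Config,
                 eye_centers=None, detector=None) -> EyeRegion:
    """Locate the eyes according to the configured mode.

    ``eye_centers`` (a pair of (x, y) points) always wins; otherwise a
    custom ``detector`` or the configured mode (template blobs or a
    user-supplied cascade) provides candidate rectangles for
    :func:`lenstrace.preprocess.detect_eyes`.
    """
    if eye_centers is not None:
        left, right = eye_centers
        return eyes_from_centers(left, right,
                                 rect_width_ipd=cfg.eyes.rect_width_ipd,
                                 rect_height_ipd=cfg.eyes.rect_height_ipd,
                                 max_tilt_deg=cfg.eyes.max_tilt_deg)
    if detector is None:
        if cfg.eyes.mode == "template":
            detector = template_eye_candidates
        elif cfg.eyes.mode == "cascade":
            if not cfg.eyes.cascade_path:
                raise EyeDetectionError("eyes.mode=cascade requires eyes.cascade_path")
            detector = lambda img: cascade_eye_candidates(img, cfg.eyes.cascade_path)
        else:
            raise EyeDetectionError("eyes.mode=supplied requires explicit eye centers")
    return detect_eyes(image, detector, max_tilt_deg=cfg.eyes.max_tilt_deg)


def extract_lenses(image: np.ndarray, db: ShapeDatabase, cfg: Config,
                   rng: np.random.Generator, eye_centers=None,
                   detector=None) -> ExtractionResult:
    """Full extraction pipeline on a grayscale facial image.

    eyes -> ROI -> Canny -> distance transform, then per shape class:
    Monte Carlo sampling, clustering, best-cluster selection and random
    walk refinement.  The final result is the class solution with the
    minimal combined score; raises :class:`ExtractionError` when no class
    yields a valid hypothesis or the winner's mean edge distance exceeds
    ``pipeline.reject_score``.
    """
    eyes = resolve_eyes(image, cfg, eye_centers=eye_centers, detector=detector)
    roi = eyeglass_roi(eyes, cfg.roi.delta, image_shape=image.shape)
    edges = edge_map(image, cfg.canny.low, cfg.canny.high, cfg.canny.sigma, roi=roi)
    df = distance_field(edges)
    fifths = face_fifths(eyes)
    pm = ProposalModel.from_config(cfg, eyes.ipd)

    class_scores: dict[str, float | None] = {}
    best: GlassesHypothesis | None = None
    for cls in ShapeClass:
        scored = monte_carlo_search(df, eyes, roi, fifths, db, cls, cfg, rng)
        if not scored:
            class_scores[cls.value] = None
            continue
        clusters = cluster_hypotheses(scored, alpha=cfg.search.alpha)
        x0 = select_best(clusters)
        refined = random_walk_refine(x0, df, eyes, roi, fifths, pm, db, cfg, rng)
        class_scores[cls.value] = refined.score.combined
        if best is None or refined.score.combined < best.score.combined:
            best = refined

    if best is None:
        raise ExtractionError("no valid lens hypothesis in any shape class")
    if best.score.combined > cfg.pipeline.reject_score:
        raise ExtractionError(
            f"best mean edge distance {best.score.combined:.2f} px exceeds "
            f"reject threshold {cfg.pipeline.reject_score} px")
    return ExtractionResult(left_contour=best.left_contour,
                            right_contour=best.right_contour,
                            hypothesis=best, score=best.score,
                            class_scores=class_scores, eyes=eyes, roi=roi)
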