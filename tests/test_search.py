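"""Monte Carlo sampling, hypothesis geometry, clustering and selection."""

import numpy as np
import pytest

from lenstrace import matching as mt
from lenstrace import search as sr
from lenstrace.geometry import Rect
from lenstrace.shape_db import ShapeClass


class TestSampling:
    def test_support_and_mean(self, db, cfg, elliptic_scene):
        eyes = elliptic_scene["eyes"]
        rng = np.random.default_rng(0)
        ipd = eyes.ipd
        box = cfg.search.centroid_box_ipd * ipd
        sizes, betas = [], []
        for i in range(2000):
            h = sr.sample_hypothesis(ShapeClass.ELLIPTIC, eyes, db, cfg, rng, i)
            cx, cy = h.left.centroid
            assert abs(cx - eyes.left_center[0]) <= box
            assert abs(cy - eyes.left_center[1]) <= box
            assert abs(h.right_cx - eyes.right_center[0]) <= box
            assert cfg.search.size_min_ipd * ipd <= h.left.size <= cfg.search.size_max_ipd * ipd
            assert 0.0 <= h.left.beta <= 1.0
            assert h.left.cls is ShapeClass.ELLIPTIC
            sizes.append(h.left.size)
            betas.append(h.left.beta)
        mean_expected = 0.5 * (cfg.search.size_min_ipd + cfg.search.size_max_ipd) * ipd
        half_range = 0.5 * (cfg.search.size_max_ipd - cfg.search.size_min_ipd) * ipd
        sem = half_range / np.sqrt(3) / np.sqrt(len(sizes))
        assert abs(np.mean(sizes) - mean_expected) < 3 * sem

    def test_fixed_seed_replays(self, db, cfg, elliptic_scene):
        eyes = elliptic_scene["eyes"]
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(31)
            runs.append([sr.sample_hypothesis(ShapeClass.RECTANGULAR, eyes, db, cfg, rng)
                         for _ in range(20)])
        for a, b in zip(*runs):
            assert a.left == b.left
            assert a.right_cx == b.right_cx

    def test_right_rim_is_mirrored_left(self, db, cfg, elliptic_scene):
        eyes = elliptic_scene["eyes"]
        h = sr.sample_hypothesis(ShapeClass.ASYMMETRIC, eyes, db, cfg,
                                 np.random.default_rng(5))
        mirrored_x = h.right_cx + (h.left.centroid[0] - h.left_contour[:, 0])
        np.testing.assert_allclose(h.right_contour[:, 0], mirrored_x, atol=1e-9)
        np.testing.assert_allclose(h.right_contour[:, 1], h.left_contour[:, 1],
                                   atol=1e-9)

    def test_batch_build_matches_descriptor_route(self, db, cfg, elliptic_scene):
        """The vectorized mirror construction equals the explicit
        morph/place/flip/translate chain in descriptor space."""
        eyes = elliptic_scene["eyes"]
        for seed in range(5):
            h = sr.sample_hypothesis(ShapeClass.RECTANGULAR, eyes, db, cfg,
                                     np.random.default_rng(seed))
            left, right = sr.build_contours(db, h.left, h.right_cx,
                                            cfg.descriptors.n_points)
            np.testing.assert_allclose(h.left_contour, left, atol=1e-9)
            np.testing.assert_allclose(h.right_contour, right, atol=1e-9)

    def test_batch_validation_matches_single(self, db, cfg, elliptic_scene):
        eyes, roi, fifths = (elliptic_scene[k] for k in ("eyes", "roi", "fifths"))
        rng = np.random.default_rng(17)
        params = sr._sample_params(ShapeClass.ELLIPTIC, eyes, db, cfg, rng, 300)
        hyps = sr._build_batch(db, params, cfg)
        left = np.stack([h.left_contour for h in hyps])
        right = np.stack([h.right_contour for h in hyps])
        mask = sr._batch_valid_mask(left, right, eyes, roi, fifths, 0.25)
        singles = np.array([mt.validate_hypothesis(h.left_contour, h.right_contour,
                                                   eyes, roi, fifths)[0]
                            for h in hyps])
        np.testing.assert_array_equal(mask, singles)


class TestMonteCarloSearch:
    def test_recovers_clean_elliptic_scene(self, db, cfg, elliptic_scene):
        """The sampling stage brackets the rims (coarse, single-digit mean
        edge distance over a ~100 px search box) and refinement then brings
        the bracketed solution under 2 px."""
        from lenstrace import refine as rf
        scored = sr.monte_carlo_search(
            elliptic_scene["df"], elliptic_scene["eyes"], elliptic_scene["roi"],
            elliptic_scene["fifths"], db, ShapeClass.ELLIPTIC, cfg,
            np.random.default_rng(2))
        assert scored
        best = min(h.score.combined for h in scored)
        assert best < 8.0
        x0 = sr.select_best(sr.cluster_hypotheses(scored, cfg.search.alpha))
        pm = rf.ProposalModel.from_config(cfg, elliptic_scene["eyes"].ipd)
        refined = rf.random_walk_refine(
            x0, elliptic_scene["df"], elliptic_scene["eyes"],
            elliptic_scene["roi"], elliptic_scene["fifths"], pm, db, cfg,
            np.random.default_rng(3))
        assert refined.score.combined < 2.0

    def test_all_kept_hypotheses_valid(self, db, cfg, elliptic_scene):
        scored = sr.monte_carlo_search(
            elliptic_scene["df"], elliptic_scene["eyes"], elliptic_scene["roi"],
            elliptic_scene["fifths"], db, ShapeClass.RECTANGULAR, cfg,
            np.random.default_rng(3))
        for h in scored[:50]:
            ok, reason = mt.validate_hypothesis(
                h.left_contour, h.right_contour, elliptic_scene["eyes"],
                elliptic_scene["roi"], elliptic_scene["fifths"])
            assert ok, reason
            assert h.score is not None


class TestRectOverlap:
    def test_identical(self):
        r = Rect(3, 4, 10, 10)
        assert sr.rect_overlap_fraction(r, r) == 1.0

    def test_disjoint(self):
        assert sr.rect_overlap_fraction(Rect(0, 0, 10, 10), Rect(30, 0, 10, 10)) == 0.0

    def test_unit_shift_of_square(self):
        a = Rect(0, 0, 10, 10)
        b = Rect(1, 0, 10, 10)
        assert sr.rect_overlap_fraction(a, b) == pytest.approx(0.9)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            sr.rect_overlap_fraction(Rect(0, 0, 0, 10), Rect(0, 0, 5, 5))


def _stub_hypothesis(bbox: Rect, score: float, gen_index: int, cls=ShapeClass.ELLIPTIC):
    """Hypothesis stub whose contour is its bounding rectangle."""
    contour = np.array([[bbox.x, bbox.y], [bbox.x1, bbox.y],
                        [bbox.x1, bbox.y1], [bbox.x, bbox.y1]])
    lens = sr.LensHypothesis(cls=cls, centroid=tuple(bbox.center), size=bbox.w / 2,
                             s1_id="a", s2_id="b", beta=0.5)
    return sr.GlassesHypothesis(left=lens, right_cx=bbox.center[0],
                                left_contour=contour, right_contour=contour,
                                score=mt.MatchScore(score, score),
                                gen_index=gen_index)


class TestClustering:
    def test_copies_collapse_to_one_cluster(self):
        hyps = [_stub_hypothesis(Rect(0, 0, 20, 20), 1.0 + 0.1 * i, i)
                for i in range(6)]
        clusters = sr.cluster_hypotheses(hyps, alpha=0.9)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 6

    def test_disjoint_stay_singletons(self):
        hyps = [_stub_hypothesis(Rect(0, 0, 10, 10), 1.0, 0),
                _stub_hypothesis(Rect(50, 50, 10, 10), 2.0, 1)]
        assert len(sr.cluster_hypotheses(hyps, alpha=0.9)) == 2

    def test_merge_trace_three_hypotheses(self):
        a = _stub_hypothesis(Rect(0, 0, 20, 20), 1.0, 0)
        b = _stub_hypothesis(Rect(1, 0, 20, 20), 1.1, 1)    # overlap 0.95 with a
        c = _stub_hypothesis(Rect(10, 0, 20, 20), 0.9, 2)   # overlap 0.50 with a
        clusters = sr.cluster_hypotheses([a, b, c], alpha=0.9)
        sizes = sorted(len(cl.members) for cl in clusters)
        assert sizes == [1, 2]
        pair = next(cl for cl in clusters if len(cl.members) == 2)
        assert {m.gen_index for m in pair.members} == {0, 1}

    def test_partition_property(self, db, cfg, elliptic_scene):
        scored = sr.monte_carlo_search(
            elliptic_scene["df"], elliptic_scene["eyes"], elliptic_scene["roi"],
            elliptic_scene["fifths"], db, ShapeClass.ELLIPTIC, cfg,
            np.random.default_rng(9))
        clusters = sr.cluster_hypotheses(scored, alpha=cfg.search.alpha)
        seen = [m.gen_index for cl in clusters for m in cl.members]
        assert sorted(seen) == sorted(h.gen_index for h in scored)
        for cl in clusters:
            for m in cl.members:
                assert cl.bbox.contains_rect(m.bbox)

    def test_deterministic_given_order(self):
        rng = np.random.default_rng(12)
        hyps = [_stub_hypothesis(Rect(rng.uniform(0, 40), rng.uniform(0, 40), 20, 20),
                                 rng.uniform(0, 5), i) for i in range(40)]
        a = sr.cluster_hypotheses(hyps, alpha=0.9)
        b = sr.cluster_hypotheses(hyps, alpha=0.9)
        assert [[m.gen_index for m in cl.members] for cl in a] \
            == [[m.gen_index for m in cl.members] for cl in b]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sr.cluster_hypotheses([], alpha=0.9)


class TestSelection:
    def test_single_cluster_returns_best_member(self):
        hyps = [_stub_hypothesis(Rect(0, 0, 20, 20), s, i)
                for i, s in enumerate([2.0, 0.7, 1.4])]
        clusters = sr.cluster_hypotheses(hyps, alpha=0.9)
        assert sr.select_best(clusters).gen_index == 1

    def test_cluster_first_selection_suppresses_lone_outlier(self):
        # dense true cluster (mean 1.0) vs a cluster holding one lucky decoy
        # hypothesis (0.5) dragged down by its bad neighbors (mean 3.0)
        true = [_stub_hypothesis(Rect(0, 0, 20, 20), s, i)
                for i, s in enumerate([0.9, 1.0, 1.1])]
        decoy = [_stub_hypothesis(Rect(100, 0, 20, 20), s, 3 + i)
                 for i, s in enumerate([0.5, 4.0, 4.5])]
        best = sr.select_best(sr.cluster_hypotheses(true + decoy, alpha=0.9))
        assert best.gen_index == 0  # best member of the TRUE cluster

    def test_tie_broken_by_generation_index(self):
        hyps = [_stub_hypothesis(Rect(0, 0, 20, 20), 1.0, i) for i in range(4)]
        assert sr.select_best(sr.cluster_hypotheses(hyps, alpha=0.9)).gen_index == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sr.select_best([])
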