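"""Fourier descriptor transforms: round trips, invariances, morphing, flipping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lenstrace import fourier_shape as fs
from lenstrace.errors import ContourError, DegenerateShapeError, DescriptorError

from conftest import make_circle, random_polygon


def brute_force_descriptors(points, n_keep):
    """O(N^2) direct-summation DFT oracle for the forward transform."""
    pts = np.asarray(points, float)
    n = len(pts)
    z = pts[:, 0] + 1j * pts[:, 1]
    idx = fs.truncation_indices(n_keep)
    coeffs = np.array([
        sum(z[i] * np.exp(-2j * np.pi * k * i / n) for i in range(n))
        for k in idx
    ])
    return idx, coeffs


def brute_force_reconstruct(desc, n_points):
    """O(N^2) direct-summation oracle for the inverse transform."""
    z = np.array([
        sum(c * np.exp(2j * np.pi * k * i / n_points)
            for k, c in zip(desc.indices, desc.coeffs)) / desc.n_points
        for i in range(n_points)
    ])
    return np.column_stack([z.real, z.imag])


class TestForwardTransform:
    def test_c0_is_point_sum(self):
        square = np.array([[9.5, 19.5], [10.5, 19.5], [10.5, 20.5], [9.5, 20.5]])
        d = fs.contour_to_descriptors(square, 4)
        assert d.coeff(0) == pytest.approx(40 + 80j)

    def test_circle_has_single_harmonic(self):
        d = fs.contour_to_descriptors(make_circle(radius=5.0, n=64), 64)
        assert abs(d.coeff(1)) == pytest.approx(320.0)
        others = d.coeffs[np.abs(d.indices) > 1]
        assert np.max(np.abs(others)) < 1e-9

    def test_parseval_identity(self):
        rng = np.random.default_rng(3)
        pts = random_polygon(rng)
        z = pts[:, 0] + 1j * pts[:, 1]
        d = fs.contour_to_descriptors(pts, 64)
        assert np.sum(np.abs(z) ** 2) == pytest.approx(
            np.sum(np.abs(d.coeffs) ** 2) / 64, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(16, 65))
        pts = random_polygon(rng, n=n)
        d = fs.contour_to_descriptors(pts, min(14, n))
        idx, coeffs = brute_force_descriptors(pts, min(14, n))
        assert np.array_equal(d.indices, idx)
        np.testing.assert_allclose(d.coeffs, coeffs, atol=1e-9 * np.abs(coeffs).max())

    def test_rejects_bad_input(self):
        with pytest.raises(ContourError):
            fs.contour_to_descriptors(np.array([[0, 0], [1, 1]]), 2)
        with pytest.raises(DescriptorError):
            fs.contour_to_descriptors(make_circle(n=8), 1)
        with pytest.raises(DescriptorError):
            fs.contour_to_descriptors(make_circle(n=8), 9)


class TestInverseTransform:
    def test_full_round_trip_is_identity(self):
        rng = np.random.default_rng(7)
        pts = random_polygon(rng)
        d = fs.contour_to_descriptors(pts, 64)
        rec = fs.descriptors_to_contour(d, 64)
        assert np.abs(rec - pts).max() < 1e-9

    def test_matches_brute_force_inverse(self):
        rng = np.random.default_rng(9)
        pts = random_polygon(rng, n=32)
        d = fs.contour_to_descriptors(pts, 14)
        fast = fs.descriptors_to_contour(d, 32)
        slow = brute_force_reconstruct(d, 32)
        assert np.abs(fast - slow).max() < 1e-9

    def test_two_coefficients_give_a_circle(self):
        rng = np.random.default_rng(11)
        pts = random_polygon(rng)
        d = fs.contour_to_descriptors(pts, 2)
        rec = fs.descriptors_to_contour(d, 64)
        radii = np.linalg.norm(rec - rec.mean(axis=0), axis=1)
        assert radii.max() - radii.min() < 1e-6

    def test_truncation_error_non_increasing(self, db):
        rim = fs.descriptors_to_contour(
            fs.place_descriptors(db.get("rect_03").desc, (50, 40), 30), 64)
        devs = []
        for n_keep in (2, 6, 14, 22, 32):
            rec = fs.descriptors_to_contour(fs.contour_to_descriptors(rim, n_keep), 64)
            devs.append(np.abs(rec - rim).max())
        assert all(b <= a + 1e-12 for a, b in zip(devs, devs[1:]))
        assert devs[-1] < 1e-9  # rim is 14-band-limited, so 14+ is exact

    def test_rejects_degenerate_requests(self):
        d = fs.contour_to_descriptors(make_circle(), 4)
        with pytest.raises(ContourError):
            fs.descriptors_to_contour(d, 2)


class TestNormalization:
    def test_normalized_first_harmonic_is_unit(self):
        d = fs.contour_to_descriptors(make_circle(radius=3.0, center=(7, 8)), 14)
        n = fs.normalize_descriptors(d)
        assert abs(n.coeff(1)) == pytest.approx(1.0)
        assert 0 not in n.indices

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(dx=st.floats(-100, 100), dy=st.floats(-100, 100),
           alpha=st.floats(0.1, 10.0))
    def test_translation_and_scale_invariance(self, dx, dy, alpha):
        pts = random_polygon(np.random.default_rng(13))
        moved = alpha * pts + np.array([dx, dy])
        n0 = fs.normalize_descriptors(fs.contour_to_descriptors(pts, 14))
        n1 = fs.normalize_descriptors(fs.contour_to_descriptors(moved, 14))
        np.testing.assert_allclose(n1.coeffs, n0.coeffs, atol=1e-9)

    def test_degenerate_shape_rejected(self):
        # all points identical: no first-harmonic extent
        pts = np.ones((8, 2))
        with pytest.raises(DegenerateShapeError):
            fs.normalize_descriptors(fs.contour_to_descriptors(pts, 4))


class TestPlacement:
    def test_place_inverts_normalization(self):
        pts = random_polygon(np.random.default_rng(17))
        d = fs.contour_to_descriptors(pts, 14)
        placed = fs.place_descriptors(fs.normalize_descriptors(d),
                                      fs.centroid(d), fs.first_harmonic_radius(d))
        r0 = fs.descriptors_to_contour(d, 64)
        r1 = fs.descriptors_to_contour(placed, 64)
        assert np.abs(r1 - r0).max() < 1e-6

    def test_place_at_origin_centers_the_contour(self, db):
        placed = fs.place_descriptors(db.get("ellip_00").desc, (0.0, 0.0), 40.0)
        rec = fs.descriptors_to_contour(placed, 64)
        np.testing.assert_allclose(rec.mean(axis=0), [0, 0], atol=1e-9)

    def test_size_doubling_scales_about_centroid(self, db):
        norm = db.get("ellip_01").desc
        c = (10.0, -5.0)
        r1 = fs.descriptors_to_contour(fs.place_descriptors(norm, c, 30.0), 64)
        r2 = fs.descriptors_to_contour(fs.place_descriptors(norm, c, 60.0), 64)
        np.testing.assert_allclose(r2 - np.array(c), 2 * (r1 - np.array(c)), atol=1e-9)

    def test_rejects_bad_size_and_state(self, db):
        norm = db.get("rect_00").desc
        with pytest.raises(DescriptorError):
            fs.place_descriptors(norm, (0, 0), 0.0)
        placed = fs.place_descriptors(norm, (0, 0), 1.0)
        with pytest.raises(DescriptorError):
            fs.place_descriptors(placed, (0, 0), 1.0)  # not normalized


class TestMorphing:
    def test_endpoints_are_exact(self, db):
        d1 = db.get("rect_00").desc
        d2 = db.get("rect_01").desc
        np.testing.assert_array_equal(fs.morph_descriptors(d1, d2, 1.0).coeffs, d1.coeffs)
        np.testing.assert_array_equal(fs.morph_descriptors(d1, d2, 0.0).coeffs, d2.coeffs)

    def test_self_morph_is_identity(self, db):
        d = db.get("asym_02").desc
        for beta in (0.0, 0.3, 0.77, 1.0):
            np.testing.assert_allclose(fs.morph_descriptors(d, d, beta).coeffs,
                                       d.coeffs, atol=1e-12)

    def test_reconstruction_continuous_in_beta(self, db):
        d1 = db.get("ellip_00").desc
        d2 = db.get("ellip_05").desc
        betas = np.linspace(0, 1, 21)
        recs = [fs.descriptors_to_contour(
            fs.place_descriptors(fs.morph_descriptors(d1, d2, b), (0, 0), 40), 64)
            for b in betas]
        steps = [np.abs(b - a).max() for a, b in zip(recs, recs[1:])]
        assert max(steps) < 5.0  # small beta step -> small shape step

    def test_rejects_mismatches(self, db):
        d1 = db.get("rect_00").desc
        with pytest.raises(DescriptorError):
            fs.morph_descriptors(d1, d1, 1.5)
        unnorm = fs.place_descriptors(d1, (0, 0), 10.0)
        with pytest.raises(DescriptorError):
            fs.morph_descriptors(d1, unnorm, 0.5)


class TestHorizontalFlip:
    def test_involution(self, db):
        d = db.get("asym_03").desc
        dd = fs.hflip_descriptors(fs.hflip_descriptors(d))
        assert np.array_equal(dd.indices, d.indices)
        np.testing.assert_allclose(dd.coeffs, d.coeffs, atol=1e-12)

    def test_circle_maps_to_itself(self):
        d = fs.contour_to_descriptors(make_circle(radius=4.0, center=(3, 9)), 14)
        rec = fs.descriptors_to_contour(fs.hflip_descriptors(d), 256)
        radii = np.linalg.norm(rec - [3, 9], axis=1)
        np.testing.assert_allclose(radii, 4.0, atol=1e-9)

    def test_mirrors_point_set_about_centroid(self, db):
        # asymmetric rim: x -> 2*cx - x, y unchanged, as point sets
        placed = fs.place_descriptors(db.get("asym_01").desc, (20.0, 30.0), 35.0)
        orig = fs.descriptors_to_contour(placed, 64)
        flip = fs.descriptors_to_contour(fs.hflip_descriptors(placed), 64)
        expected = np.column_stack([2 * 20.0 - orig[:, 0], orig[:, 1]])
        # traversal order may differ: compare as sorted point sets
        key = lambda a: a[np.lexsort((a[:, 1], a[:, 0]))]
        np.testing.assert_allclose(key(flip), key(expected), atol=1e-9)

    def test_traced_fixture_flip_round_trip(self):
        from lenstrace.shape_db import reference_entries
        for entry in reference_entries():
            d = entry.desc
            dd = fs.hflip_descriptors(fs.hflip_descriptors(d))
            np.testing.assert_allclose(dd.coeffs, d.coeffs, atol=1e-12)
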