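"""Fourier-descriptor representation of closed contours.

A closed contour with points (x(i), y(i)) is read as the complex sequence
z(i) = x(i) + j*y(i) (image coordinates: x rightward is the real axis, y
downward the imaginary axis).  Its Fourier descriptors are the plain,
unnormalized DFT coefficients

    c(k) = sum_i z(i) * exp(-2*pi*j*k*i/N)

so c(0) = N * centroid and, for a circle of radius r traversed once,
|c(1)| = N * r.  Low frequencies carry the coarse outline, high frequencies
the detail; truncating to the lowest few |k| gives a smooth approximation of
the rim.  All geometric transforms used by the lens model — translation,
scaling, horizontal flipping and shape morphing — are performed directly in
descriptor space.

Descriptor sets are made translation-invariant by dropping c(0) and
scale-invariant by dividing every coefficient by the scalar magnitude |c(1)|.
No rotation or start-point normalization is applied: rims are matched in
image orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ContourError, DegenerateShapeError, DescriptorError

#: number of resampled contour points shared by all database shapes
DEFAULT_N_POINTS = 64
#: number of retained Fourier descriptors for rim shapes
DEFAULT_N_DESCRIPTORS = 14


@dataclass(frozen=True)
class DescriptorSet:
    """Truncated set of complex Fourier coefficients of a closed contour.

    Parameters
    ----------
    indices : ndarray of int
        Signed frequency indices k, in canonical truncation order
        (0, +1, -1, +2, -2, ...; see :func:`truncation_indices`).
    coeffs : ndarray of complex
        Coefficients c(k), aligned with ``indices``.
    n_points : int
        Number of contour samples N the forward transform was computed from;
        also the normalization constant of the inverse transform.
    normalized : bool
        True once c(0) has been dropped and all coefficients divided by
        |c(1)| (translation- and scale-invariant form).
    """

    indices: np.ndarray
    coeffs: np.ndarray
    n_points: int
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=complex))
        if self.indices.shape != self.coeffs.shape:
            raise DescriptorError("indices and coeffs must have equal length")
        if len(np.unique(self.indices)) != len(self.indices):
            raise DescriptorError("duplicate frequency index")
        if self.normalized and 0 in self.indices:
            raise DescriptorError("normalized descriptor set must not contain c(0)")

    def __len__(self) -> int:
        return len(self.indices)

    def coeff(self, k: int) -> complex:
        """Return c(k), or 0 if frequency k is not retained."""
        hit = np.nonzero(self.indices == k)[0]
        return complex(self.coeffs[hit[0]]) if hit.size else 0j

    def to_dict(self) -> dict:
        """JSON-serializable form (re/im split keeps files human-readable)."""
        return {
            "n_points": int(self.n_points),
            "indices": [int(k) for k in self.indices],
            "re": [float(c.real) for c in self.coeffs],
            "im": [float(c.imag) for c in self.coeffs],
            "normalized": bool(self.normalized),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorSet":
        coeffs = np.asarray(d["re"], float) + 1j * np.asarray(d["im"], float)
        return cls(
            indices=np.asarray(d["indices"], int),
            coeffs=coeffs,
            n_points=int(d["n_points"]),
            normalized=bool(d["normalized"]),
        )


def truncation_indices(n_keep: int) -> np.ndarray:
    """Canonical low-frequency truncation order: 0, +1, -1, +2, -2, ...

    Keeps the ``n_keep`` coefficients of lowest absolute frequency,
    symmetric about zero, favoring +k on ties (so n_keep=14 retains
    k in {0, ±1, ..., ±6, +7}).
    """
    if n_keep < 2:
        raise DescriptorError("need at least 2 descriptors (c(0) and c(1))")
    out = [0]
    k = 1
    while len(out) < n_keep:
        out.append(k)
        if len(out) < n_keep:
            out.append(-k)
        k += 1
    return np.asarray(out, dtype=int)


def as_contour(points) -> np.ndarray:
    """Validate and return a contour as an (N, 2) float array of (x, y)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContourError("contour must be an (N, 2) array of points")
    if pts.shape[0] < 3:
        raise ContourError("contour needs at least 3 points")
    if not np.all(np.isfinite(pts)):
        raise ContourError("contour has non-finite coordinates")
    return pts


def resample_contour(points, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Resample a closed polyline to ``n_points`` arc-length-equidistant points.

    All database shapes are resampled to a common N before the transform so
    their descriptor sets are commensurable for morphing.
    """
    pts = as_contour(points)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ContourError("degenerate contour with zero perimeter")
    t = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def contour_to_descriptors(points, n_keep: int) -> DescriptorSet:
    """Forward transform: keep the ``n_keep`` lowest-|k| DFT coefficients.

    The DFT is unnormalized, so c(0) = N * centroid and coefficients scale
    linearly with the contour.
    """
    pts = as_contour(points)
    n = pts.shape[0]
    if n_keep > n:
        raise DescriptorError(f"n_keep={n_keep} exceeds point count {n}")
    z = pts[:, 0] + 1j * pts[:, 1]
    full = np.fft.fft(z)  # c(k) = sum z(i) e^{-2 pi j k i / N}
    idx = truncation_indices(n_keep)
    # negative frequencies live at positions N+k in the FFT output
    coeffs = full[idx % n]
    return DescriptorSet(indices=idx, coeffs=coeffs, n_points=n, normalized=False)


def descriptors_to_contour(desc: DescriptorSet, n_points: int) -> np.ndarray:
    """Inverse transform, evaluating the truncated Fourier series.

        z(i) = (1/N) * sum_k c(k) * exp(+2*pi*j*k*i/n_points)

    with N = ``desc.n_points``; frequencies missing from the truncated set
    are treated as zero.  With the full coefficient set and
    ``n_points == N`` this is the exact inverse DFT.
    """
    if len(desc) < 2:
        raise DescriptorError("need at least 2 coefficients to reconstruct")
    if n_points < 3:
        raise ContourError("need at least 3 reconstruction points")
    i = np.arange(n_points)
    phases = np.exp(2j * np.pi * np.outer(desc.indices, i) / n_points)
    z = (desc.coeffs @ phases) / desc.n_points
    return np.column_stack([z.real, z.imag])


def centroid(desc: DescriptorSet) -> np.ndarray:
    """Centroid of the reconstructed contour: c(0)/N (origin if c(0) absent)."""
    c0 = desc.coeff(0) / desc.n_points
    return np.array([c0.real, c0.imag])


def first_harmonic_radius(desc: DescriptorSet) -> float:
    """Radius of the first-harmonic circle, |c(1)|/N — the shape's size scale."""
    return abs(desc.coeff(1)) / desc.n_points


def normalize_descriptors(desc: DescriptorSet) -> DescriptorSet:
    """Translation/scale-invariant form: drop c(0), divide by |c(1)|.

    Division is by the scalar magnitude, not the complex value, so the
    shape's orientation and phase are preserved.
    """
    c1 = abs(desc.coeff(1))
    if c1 <= 0:
        raise DegenerateShapeError("cannot normalize: |c(1)| = 0")
    keep = desc.indices != 0
    return DescriptorSet(
        indices=desc.indices[keep],
        coeffs=desc.coeffs[keep] / c1,
        n_points=desc.n_points,
        normalized=True,
    )


def place_descriptors(norm: DescriptorSet, centroid_xy, size: float) -> DescriptorSet:
    """Instantiate a normalized shape at a position and size (inverse of
    normalization).

    ``size`` is the first-harmonic radius in pixels (roughly the lens
    half-width): coefficients are multiplied by ``size * N`` so that
    |c(1)|/N = size, and c(0) is set to N * centroid.
    """
    if not norm.normalized:
        raise DescriptorError("place_descriptors expects a normalized set")
    if size <= 0:
        raise DescriptorError("size must be positive")
    cx, cy = float(centroid_xy[0]), float(centroid_xy[1])
    n = norm.n_points
    indices = np.concatenate([[0], norm.indices])
    coeffs = np.concatenate([[n * (cx + 1j * cy)], norm.coeffs * (size * n)])
    return DescriptorSet(indices=indices, coeffs=coeffs, n_points=n, normalized=False)


def translate_descriptors(desc: DescriptorSet, centroid_xy) -> DescriptorSet:
    """Move an unnormalized set to a new centroid by rewriting c(0) only."""
    if 0 not in desc.indices:
        raise DescriptorError("translate requires c(0) (unnormalized set)")
    cx, cy = float(centroid_xy[0]), float(centroid_xy[1])
    coeffs = desc.coeffs.copy()
    coeffs[desc.indices == 0] = desc.n_points * (cx + 1j * cy)
    return replace(desc, coeffs=coeffs)


def morph_descriptors(d1: DescriptorSet, d2: DescriptorSet, beta: float) -> DescriptorSet:
    """Shape morphing: coefficient-wise convex combination beta*d1 + (1-beta)*d2.

    Exploits the closure of Fourier series under addition: the morph of two
    closed-contour descriptor sets is itself a valid descriptor set, giving a
    continuum of intermediate rim shapes between two database samples.
    """
    if not 0.0 <= beta <= 1.0:
        raise DescriptorError(f"morph factor beta={beta} outside [0, 1]")
    if d1.normalized != d2.normalized or d1.n_points != d2.n_points:
        raise DescriptorError("morph operands have mismatched normalization state")
    if not np.array_equal(d1.indices, d2.indices):
        raise DescriptorError("morph operands have mismatched frequency index sets")
    return replace(d1, coeffs=beta * d1.coeffs + (1.0 - beta) * d2.coeffs)


def hflip_descriptors(desc: DescriptorSet) -> DescriptorSet:
    """Mirror a shape about the vertical axis through its centroid.

    In point space the mirror is z -> 2*cx - conj(z); in descriptor space
    this maps c(k) -> -conj(c(-k)) for k != 0 and leaves c(0) (the centroid)
    unchanged.  The frequency index set is negated accordingly, so flipping
    twice restores the original set exactly.  The reconstructed point set is
    the mirrored original point set; traversal order reverses.
    """
    flipped_idx = -desc.indices
    c0 = desc.coeff(0)
    coeffs = -np.conj(desc.coeffs)
    if 0 in desc.indices:
        coeffs[desc.indices == 0] = c0  # centroid is preserved by the mirror
    order = np.argsort(_canonical_rank(flipped_idx))
    return DescriptorSet(
        indices=flipped_idx[order],
        coeffs=coeffs[order],
        n_points=desc.n_points,
        normalized=desc.normalized,
    )


def _canonical_rank(indices: np.ndarray) -> np.ndarray:
    # rank of each signed frequency in the 0, +1, -1, +2, -2, ... order
    return 2 * np.abs(indices) - (indices > 0)
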