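"""The eyeglasses shape database.

Rim shapes are stored as normalized (translation/scale-invariant) Fourier
descriptor sets of the *left* rim only; the right rim is always derived by
horizontal flipping, so left-right frame symmetry is built into the model.
Shapes are grouped into three classes by similarity — rectangular
symmetric, elliptic symmetric and asymmetric — and morphing is only ever
performed within a class, so every convex combination remains a plausible
rim.

The built-in database combines three manually traced reference rims (one
per class, shipped as a JSON fixture) with procedurally generated families:
rounded rectangles, superellipses, and vertically skewed superellipse
blends.  Procedural generation is deterministic (fixed internal seed) so
the database is identical across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

from . import fourier_shape as fs
from .errors import DatabaseError

_NORM_TOL = 1e-6


class ShapeClass(str, Enum):
    """The three rim shape classes."""

    RECTANGULAR = "rectangular_symmetric"
    ELLIPTIC = "elliptic_symmetric"
    ASYMMETRIC = "asymmetric"


@dataclass(frozen=True)
class ShapeEntry:
    id: str
    cls: ShapeClass
    desc: fs.DescriptorSet


@dataclass
class ShapeDatabase:
    """Validated collection of normalized left-rim descriptor sets."""

    entries: list[ShapeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = set()
        ref_idx = None
        for e in self.entries:
            if e.id in ids:
                raise DatabaseError(f"duplicate entry id {e.id!r}")
            ids.add(e.id)
            if not e.desc.normalized:
                raise DatabaseError(f"entry {e.id!r} is not normalized")
            c1 = abs(e.desc.coeff(1))
            if abs(c1 - 1.0) > _NORM_TOL:
                raise DatabaseError(f"entry {e.id!r} has |c(1)| = {c1}, expected 1")
            if ref_idx is None:
                ref_idx = e.desc.indices
            elif not np.array_equal(e.desc.indices, ref_idx):
                raise DatabaseError(f"entry {e.id!r} has a mismatched index set")
        self._by_id = {e.id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, entry_id: str) -> ShapeEntry:
        try:
            return self._by_id[entry_id]
        except KeyError:
            raise DatabaseError(f"unknown entry id {entry_id!r}") from None

    def by_class(self, cls: ShapeClass) -> list[ShapeEntry]:
        return [e for e in self.entries if e.cls is cls]

    def classes(self) -> list[ShapeClass]:
        return [c for c in ShapeClass if self.by_class(c)]

    def save(self, path) -> None:
        payload = {
            "entries": [
                {"id": e.id, "class": e.cls.value, **e.desc.to_dict()}
                for e in self.entries
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def load_database(path) -> ShapeDatabase:
    """Load and validate a shape database JSON file."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DatabaseError(f"cannot read shape database {path}: {exc}") from exc
    entries = []
    for rec in payload.get("entries", []):
        try:
            cls = ShapeClass(rec["class"])
        except ValueError:
            raise DatabaseError(
                f"entry {rec.get('id')!r}: unknown class {rec.get('class')!r}"
            ) from None
        entries.append(ShapeEntry(id=rec["id"], cls=cls, desc=fs.DescriptorSet.from_dict(rec)))
    return ShapeDatabase(entries=entries)


def sample_shape_pair(db: ShapeDatabase, cls: ShapeClass, rng: np.random.Generator):
    """Draw two reference shapes of one class, uniformly with replacement.

    Returns the pair of :class:`ShapeEntry` (the pair may repeat an entry;
    the morph then degenerates to that shape, which is harmless).
    """
    pool = db.by_class(cls)
    if not pool:
        raise DatabaseError(f"shape class {cls.value!r} is empty")
    i, j = rng.integers(0, len(pool), size=2)
    return pool[i], pool[j]


# ---------------------------------------------------------------------------
# built-in database
# ---------------------------------------------------------------------------

def _rounded_rectangle(a: float, b: float, r: float, n: int = 256) -> np.ndarray:
    """Rounded rectangle with half-width a, half-height b, corner radius r."""
    pts = []
    # traversed with increasing parameter angle: (cos t, sin t) orientation,
    # which makes c(+1) the dominant harmonic under image-coordinate reading
    corners = [
        (a - r, b - r, 0.0),          # bottom-right (y down): angles 0..90
        (-(a - r), b - r, 90.0),      # bottom-left
        (-(a - r), -(b - r), 180.0),  # top-left
        (a - r, -(b - r), 270.0),     # top-right
    ]
    n_arc = max(4, n // 12)
    n_edge = max(4, n // 12)
    for idx, (cx, cy, a0) in enumerate(corners):
        t = np.radians(np.linspace(a0, a0 + 90.0, n_arc, endpoint=False))
        pts.append(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))
        nxt = corners[(idx + 1) % 4]
        t0 = np.radians(a0 + 90.0)
        p0 = np.array([cx + r * np.cos(t0), cy + r * np.sin(t0)])
        p1 = np.array([nxt[0] + r * np.cos(t0), nxt[1] + r * np.sin(t0)])
        lam = np.linspace(0.0, 1.0, n_edge, endpoint=False)[:, None]
        pts.append(p0 + lam * (p1 - p0))
    return np.vstack(pts)


def _superellipse(a: float, b: float, p: float, n: int = 256) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x = a * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / p)
    y = b * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / p)
    return np.column_stack([x, y])


def _skewed_blend(a: float, b_top: float, b_bot: float, p_top: float,
                  p_bot: float, shear: float, n: int = 256) -> np.ndarray:
    """Asymmetric rim: different top/bottom depth and exponent, sheared bottom."""
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    cx, sx = np.cos(t), np.sin(t)
    bottom = sx >= 0  # image coordinates: y grows downward
    b = np.where(bottom, b_bot, b_top)
    p = np.where(bottom, p_bot, p_top)
    x = a * np.sign(cx) * np.abs(cx) ** (2.0 / p)
    y = b * np.sign(sx) * np.abs(sx) ** (2.0 / p)
    x = x + shear * np.where(bottom, y / b_bot, 0.0) * a
    return np.column_stack([x, y])


def _to_entry(entry_id: str, cls: ShapeClass, points: np.ndarray,
              n_keep: int = fs.DEFAULT_N_DESCRIPTORS) -> ShapeEntry:
    pts = fs.resample_contour(points, fs.DEFAULT_N_POINTS)
    desc = fs.normalize_descriptors(fs.contour_to_descriptors(pts, n_keep))
    return ShapeEntry(id=entry_id, cls=cls, desc=desc)


def load_reference_samples() -> list[dict]:
    """Raw reference rim descriptor fixtures (verbatim values + assumed indices)."""
    text = resources.files("lenstrace.data").joinpath(
        "rim_descriptor_samples.json").read_text()
    return json.loads(text)


def reference_entries() -> list[ShapeEntry]:
    payload = load_reference_samples()
    indices = np.asarray(payload["indices"], int)
    canonical = fs.truncation_indices(fs.DEFAULT_N_DESCRIPTORS)
    out = []
    for rec in payload["samples"]:
        pairs = np.asarray(rec["pairs"], float)
        desc = fs.DescriptorSet(indices=indices,
                                coeffs=pairs[:, 0] + 1j * pairs[:, 1],
                                n_points=fs.DEFAULT_N_POINTS)
        # the traced rims carry their dominant harmonic at k = -1 (opposite
        # traversal orientation); reversing the traversal maps c(k) -> c(-k)
        if abs(desc.coeff(-1)) > abs(desc.coeff(1)):
            desc = fs.DescriptorSet(indices=-desc.indices, coeffs=desc.coeffs,
                                    n_points=desc.n_points)
        # re-truncate onto the canonical index set (missing terms are zero)
        coeffs = np.array([desc.coeff(k) for k in canonical])
        desc = fs.DescriptorSet(indices=canonical, coeffs=coeffs,
                                n_points=desc.n_points)
        out.append(ShapeEntry(id=rec["id"], cls=ShapeClass(rec["class"]),
                              desc=fs.normalize_descriptors(desc)))
    return out


def builtin_database(min_entries: int = 40) -> ShapeDatabase:
    """The built-in 40+-sample database across the three rim classes.

    Deterministic procedural families (rounded rectangles, superellipses,
    vertically skewed blends) with jittered aspect/corner/exponent
    parameters.  The manually traced reference rims (see
    :func:`reference_entries`) are *not* morphable database members: their
    recorded coefficients carry enough high-frequency energy that they
    reconstruct as self-intersecting curves under this package's index
    conventions, which would break the database invariant that every
    same-class morph is a simple closed rim.  They remain available as
    serialization and flip-test fixtures.
    """
    rng = np.random.default_rng(20131013)  # fixed: the database is a constant
    entries: list[ShapeEntry] = []

    # parameter ranges keep the three families visually distinct (class
    # membership is by shape similarity, so the classes must not overlap):
    # rectangular = flat sides with moderately rounded corners, elliptic =
    # near-true superellipses, asymmetric = aviator-like shapes with a
    # clearly deeper bottom and a pronounced nasal shear
    per_class = int(np.ceil(min_entries / 3)) + 1
    for i in range(per_class):
        aspect = rng.uniform(0.55, 0.75)
        r = rng.uniform(0.12, 0.28)
        entries.append(_to_entry(
            f"rect_{i:02d}", ShapeClass.RECTANGULAR,
            _rounded_rectangle(1.0, aspect, r * aspect)))
    for i in range(per_class):
        aspect = rng.uniform(0.60, 0.85)
        p = rng.uniform(1.9, 2.4)
        entries.append(_to_entry(
            f"ellip_{i:02d}", ShapeClass.ELLIPTIC,
            _superellipse(1.0, aspect, p)))
    for i in range(per_class):
        # two effective degrees of freedom (depth, shear): a one-dimensional
        # morph between two random anchors can then approximate any family
        # member well, which keeps the within-class search space coherent
        b_top = rng.uniform(0.45, 0.52)
        b_bot = b_top + 0.35
        shear = rng.uniform(0.10, 0.18) * (1 if rng.random() < 0.5 else -1)
        entries.append(_to_entry(
            f"asym_{i:02d}", ShapeClass.ASYMMETRIC,
            _skewed_blend(1.0, b_top, b_bot, 2.6, 2.0, shear)))
    return ShapeDatabase(entries=entries)
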