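import numpy as np
import pytest

from lenstrace import matching as mt
from lenstrace import preprocess as pp
from lenstrace import synthetic as syn
from lenstrace.config import Config
from lenstrace.shape_db import ShapeClass, builtin_database


@pytest.fixture(scope="session")
def db():
    return builtin_database()


@pytest.fixture()
def cfg():
    return Config()


def make_circle(radius=5.0, n=64, center=(0.0, 0.0)):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def random_polygon(rng, n=64, scale=20.0, center=(50.0, 50.0)):
    """Star-shaped random polygon (simple by construction)."""
    t = 2 * np.pi * np.arange(n) / n
    r = scale * (1.0 + 0.3 * rng.uniform(-1, 1, n))
    r = np.convolve(np.r_[r[-4:], r, r[:4]], np.ones(9) / 9, mode="same")[4:-4]
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


@pytest.fixture(scope="session")
def elliptic_scene(db):
    """One clean elliptic-rim scene with its preprocessing products."""
    spec = syn.random_scene_spec(np.random.default_rng(424242), db,
                                 cls=ShapeClass.ELLIPTIC)
    image, truth = syn.generate_scene(spec, db)
    eyes = pp.detect_eyes(image, pp.template_eye_candidates)
    roi = pp.eyeglass_roi(eyes, 1.5, image_shape=image.shape)
    edges = pp.edge_map(image, roi=roi)
    df = pp.distance_field(edges)
    fifths = mt.face_fifths(eyes)
    return {"spec": spec, "image": image, "truth": truth, "eyes": eyes,
            "roi": roi, "edges": edges, "df": df, "fifths": fifths}
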