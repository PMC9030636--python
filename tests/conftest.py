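import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scalafit as sf

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    """Spiral parameters of a population-average cochlea."""
    return sf.params_from_dimensions(9.1, 6.8, 2.8, turns=2.75)


@pytest.fixture(scope="session")
def template(default_params):
    """Mid-resolution template reused across read-only tests."""
    return sf.make_membrane_surface(default_params, angular_step=5.0)


@pytest.fixture(scope="session")
def coarse_template(default_params):
    return sf.make_membrane_surface(default_params, angular_step=10.0,
                                    width_samples=3)


def make_stub_template(index_value, side="right", label=""):
    """Minimal valid template for bank-construction tests (geometry-free)."""
    verts = np.array([[1, 0, 0], [1.2, 0, 0], [0, 1, 0.5],
                      [0, 1.2, 0.5], [-1, 0, 1], [-1.2, 0, 1]], float)
    faces = np.array([[0, 2, 1], [1, 2, 3], [2, 4, 3], [3, 4, 5]])
    ang = np.array([0.0, 0.0, 90.0, 90.0, 180.0, 180.0])
    wf = np.array([-0.5, 0.5, -0.5, 0.5, -0.5, 0.5])
    return sf.MembraneTemplate(verts, faces, ang, wf, index_value=index_value,
                               side=side, label=label or f"stub-{index_value}")


def random_similarity(rng, scale_range=(0.5, 2.0)):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    return sf.SimilarityTransform(rot, float(rng.uniform(*scale_range)),
                                  rng.uniform(-50, 50, 3))
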