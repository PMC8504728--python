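import numpy as np
import pytest

from pelvimetrics.morphometry import LandmarkSet
from pelvimetrics.synthetic import GeneratorConfig


@pytest.fixture
def template_coords() -> dict[str, np.ndarray]:
    """A hand-placed, anatomically plausible 11-landmark configuration (mm)."""
    return {
        "ischial_spine_L": np.array([-50.0, 0.0, 0.0]),
        "ischial_spine_R": np.array([50.0, 0.0, 0.0]),
        "ischial_tuberosity_L": np.array([-57.5, 10.0, -35.0]),
        "ischial_tuberosity_R": np.array([57.5, 10.0, -35.0]),
        "sacral_promontory": np.array([0.0, -60.0, 80.0]),
        "between_S4_S5": np.array([0.0, -55.0, 10.0]),
        "apex_S5": np.array([0.0, -50.0, 0.0]),
        "dorsal_sup_pubic_symphysis": np.array([0.0, 45.0, 60.0]),
        "dorsal_inf_pubic_symphysis": np.array([0.0, 42.0, -15.0]),
        "max_iliopectineal_L": np.array([-62.5, -5.0, 55.0]),
        "max_iliopectineal_R": np.array([62.5, -5.0, 55.0]),
    }


@pytest.fixture
def template_landmarks(template_coords) -> LandmarkSet:
    return LandmarkSet(
        specimen_id="T001", observer_id="obs1", replicate_id=1, coords=template_coords
    )


@pytest.fixture
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=12345, n_male=10, n_female=10)


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation matrix and a translation vector."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=100.0, size=3)
    return q, t


def vector_angle_deg(vertex: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Dot-product angle oracle, independent of the law-of-cosines path."""
    u, v = p1 - vertex, p2 - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
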