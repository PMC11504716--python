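import numpy as np
import pytest

from cranangles.landmarks import LandmarkPoint, LandmarkSet
from cranangles.synthetic import (SyntheticConfig, generate_angle_table,
                                  generate_landmark_sets, load_reference_stats)


@pytest.fixture(scope="session")
def reference_stats():
    return load_reference_stats()


@pytest.fixture(scope="session")
def template_specimen():
    """One noise-free synthetic male specimen in FH-aligned coordinates."""
    cfg = SyntheticConfig(n_male=1, n_female=0, noise_sd=0.0, rigid_transform=False,
                          missing_pr_rate={}, seed=0)
    return generate_landmark_sets(cfg)[0]


@pytest.fixture(scope="session")
def small_angle_table(reference_stats):
    """Synthetic 60+70 angle table at default dimorphism strength."""
    return generate_angle_table(reference_stats,
                                SyntheticConfig(n_male=60, n_female=70, seed=123))


def make_set(points, specimen_id="s1", sex=None):
    s = LandmarkSet(specimen_id, sex)
    for code, side, xyz in points:
        s.add(LandmarkPoint(code, side, tuple(float(v) for v in xyz)))
    return s


@pytest.fixture
def fh_base_points():
    """Minimal FH triad: left orbitale at y=0 plus both porions, all in z=0."""
    return [("or", "left", (85.0, 0.0, 0.0)),
            ("po", "left", (0.0, 60.0, 0.0)),
            ("po", "right", (0.0, -60.0, 0.0))]


@pytest.fixture
def rng():
    return np.random.default_rng(20240929)
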