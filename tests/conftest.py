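import numpy as np
import pytest

from otctopo import (
    PlantedTopography,
    default_synthetic_anchors,
    fit_roi_spline,
    generate_dataset,
)


@pytest.fixture(scope="session")
def topo():
    """The default study conditions: 18 subjects, 8 runs, 36x10x10 grid."""
    return PlantedTopography()


@pytest.fixture(scope="session")
def small_topo():
    """A small, quieter grid for fast volumetric tests."""
    return PlantedTopography(grid_shape=(24, 8, 8), n_subjects=6, noise_sd=0.25)


@pytest.fixture(scope="session")
def small_dataset(small_topo):
    return generate_dataset(small_topo, seed=11)


@pytest.fixture(scope="session")
def small_vector(small_topo):
    return fit_roi_spline(default_synthetic_anchors(small_topo))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
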