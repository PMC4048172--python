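import numpy as np
import pytest

from paindecode import cohort as C


def small_affine(offset=-24.0):
    return np.array([
        [2.0, 0.0, 0.0, offset],
        [0.0, 2.0, 0.0, offset],
        [0.0, 0.0, 2.0, offset],
        [0.0, 0.0, 0.0, 1.0],
    ])


@pytest.fixture(scope="session")
def small_mask():
    """Two-region mask with a few hundred voxels, cheap to simulate on."""
    return C.make_mask(
        shape=(24, 24, 24),
        region_specs=[("A", (-10.0, -10.0, -10.0), 8.0),
                      ("B", (10.0, 10.0, 10.0), 6.0)],
        affine=small_affine())


@pytest.fixture(scope="session")
def tiny_mask():
    """Single small sphere (~19 voxels) for permutation-heavy checks."""
    return C.make_mask(
        shape=(10, 10, 10),
        region_specs=[("cal", (0.0, 0.0, 0.0), 3.0)],
        affine=np.array([[2.0, 0, 0, -9.0], [0, 2.0, 0, -9.0],
                         [0, 0, 2.0, -9.0], [0, 0, 0, 1.0]]))


@pytest.fixture(scope="session")
def strong_cohort(small_mask):
    """Small strong-effect cohort: 3 informative voxels at d = 2."""
    truth = C.GroundTruth(informative_indices=(0, 150, 300),
                          effect_sizes=(-2.0, -2.0, 2.0), seed=11)
    maps, table = C.simulate_contrast_cohort(small_mask, truth,
                                             n_per_group=13)
    return maps, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
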