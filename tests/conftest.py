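import numpy as np
import pytest

from connparc.synthetic import (make_planted_truth, make_seed_geometry,
                                simulate_connectivity)


@pytest.fixture(scope="session")
def small_geometry():
    return make_seed_geometry(30, rng_seed=1)


@pytest.fixture(scope="session")
def small_truth(small_geometry):
    return make_planted_truth(small_geometry, k_true=3, n_targets=90)


@pytest.fixture(scope="session")
def small_subjects(small_geometry, small_truth):
    return simulate_connectivity(small_geometry, small_truth, n_subjects=8,
                                 streams_per_voxel=2000, rng_seed=2)


@pytest.fixture(scope="session")
def noiseless_subjects(small_geometry):
    truth = make_planted_truth(small_geometry, k_true=3, n_targets=90,
                               noise_scale=0.0)
    return truth, simulate_connectivity(small_geometry, truth, n_subjects=4,
                                        streams_per_voxel=2000, rng_seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
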