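import dataclasses

import numpy as np
import pytest

from hypoperf import PhantomSpec, make_roi_labels, simulate_truth_cbf
from hypoperf.synthetic import make_m0


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def small_spec():
    """Same anatomy, fewer frames/subjects — keeps IO-heavy tests quick."""
    return dataclasses.replace(
        PhantomSpec(seed=11), n_subjects=2, n_asl_frames=8, n_pet_repeats=2
    )


@pytest.fixture(scope="session")
def labels(spec):
    return make_roi_labels(spec)


@pytest.fixture(scope="session")
def truth_eu(spec, labels):
    return simulate_truth_cbf(spec, 0, "eu", labels)


@pytest.fixture(scope="session")
def m0_map(spec, labels):
    return make_m0(spec, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
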