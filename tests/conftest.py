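import numpy as np
import pytest

import critperturb as cp
from critperturb import fixtures, response


@pytest.fixture(scope="session")
def small_net():
    """40x40 lattice with the full connectivity kernel."""
    return cp.build_lattice(side=40, seed=7)


@pytest.fixture(scope="session")
def scaling_rec():
    rec, gt = fixtures.scaling_recording(seed=3)
    return rec, gt


@pytest.fixture(scope="session")
def scaling_counts(scaling_rec):
    rec, gt = scaling_rec
    counts = response.extract_trial_counts(rec)
    table = response.classify_responders(counts)
    return counts, table, gt


@pytest.fixture(scope="session")
def decoding_rec():
    return fixtures.decoding_recording(seed=5)


def rng(seed=0):
    return np.random.default_rng(seed)
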