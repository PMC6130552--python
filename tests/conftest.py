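import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from conncompare.io import Connectome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def symmetric_random_connectome(rng, n=10, density=0.6, modality="structural"):
    """Random weighted connectome with roughly the requested density."""
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    w = rng.uniform(0.05, 1.0, size=iu.size) * present
    m[iu, ju] = w
    m[ju, iu] = w
    return Connectome(m, modality=modality, subject_id="synth")


@pytest.fixture
def random_connectome(rng):
    return symmetric_random_connectome(rng)


@pytest.fixture(scope="session")
def null_cohort():
    """One null-configured synthetic cohort, shared across tests."""
    from conncompare.synthetic import gen_cohort, null_config
    return gen_cohort(null_config(seed=2024))


@pytest.fixture(scope="session")
def disease_cohort():
    """One large-effect disease-like synthetic cohort."""
    from conncompare.synthetic import fad_like_config, gen_cohort
    return gen_cohort(fad_like_config("large", seed=2024))
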