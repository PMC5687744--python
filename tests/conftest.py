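import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from minssm.ssm import SSMParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stable_params(rng, p, sigma_Q=0.5, sigma_R=0.2, radius=0.7):
    """Random SSM parameters with spectral radius scaled to `radius`."""
    A = rng.standard_normal((p, p))
    A *= radius / np.abs(np.linalg.eigvals(A)).max()
    L = rng.standard_normal((p, p)) / np.sqrt(p)
    Sigma = L @ L.T + 0.1 * np.eye(p)
    return SSMParameters(
        A=A, sigma_Q=sigma_Q, sigma_R=sigma_R,
        mu=rng.standard_normal(p), Sigma=Sigma,
    )


@pytest.fixture
def stable_params_factory():
    return random_stable_params
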