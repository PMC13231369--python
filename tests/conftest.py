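import numpy as np
import pytest

from solvatherm.synthetic_data import default_ground_truth, generate_dataset
from solvatherm.pipeline import analyze


@pytest.fixture(scope="session")
def zero_noise_truth():
    return default_ground_truth(seed=1, sigma_rho=0.0, sigma_u=0.0)


@pytest.fixture(scope="session")
def zero_noise_table(zero_noise_truth):
    return generate_dataset(zero_noise_truth)


@pytest.fixture(scope="session")
def zero_noise_results(zero_noise_truth, zero_noise_table):
    return analyze(zero_noise_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
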