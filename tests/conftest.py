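import numpy as np
import pytest

from medgp.data_model import Cohort, PatientSeries
from medgp.kernels import CoregWeights, MedGPModel, SMBasisKernel, lengthscale_to_v, period_to_mu


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_model(rng, Q=2, D=3, R=2, names=None):
    basis = [
        SMBasisKernel(period_to_mu(rng.uniform(20, 80)), lengthscale_to_v(rng.uniform(10, 80)))
        for _ in range(Q)
    ]
    weights = [
        CoregWeights(rng.uniform(-1, 1, size=(D, R)), rng.uniform(0.05, 0.5, size=D))
        for _ in range(Q)
    ]
    names = names or [f"c{d}" for d in range(D)]
    return MedGPModel(basis, weights, rng.uniform(0.05, 0.3, size=D), names)


def random_patient(rng, D=3, n_per_cov=(3, 8), names=None, pid="p0"):
    names = names or [f"c{d}" for d in range(D)]
    times, values = [], []
    for _ in range(D):
        n = int(rng.integers(*n_per_cov))
        times.append(np.sort(rng.uniform(0, 100, size=n)))
        values.append(rng.normal(size=n))
    return PatientSeries(pid, names, times, values)


@pytest.fixture
def small_patient(rng):
    return random_patient(rng)


@pytest.fixture
def small_model(rng):
    return random_model(rng)


@pytest.fixture
def small_cohort(rng):
    names = ["a", "b"]
    patients = [random_patient(rng, D=2, names=names, pid=f"p{i}") for i in range(4)]
    return Cohort(patients, names)
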