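import numpy as np
import pytest

from terradom.preprocess import PreprocessSpec, preprocess_table
from terradom.simulate import GeneratorConfig, generate_dataset
from terradom.tables import build_time_agnostic, build_time_aware

SMALL = GeneratorConfig(n_samples=60, n_formulas=120, seed=11)


@pytest.fixture(scope="session")
def dataset():
    """A small synthetic campaign shared across the suite."""
    return generate_dataset(SMALL)


@pytest.fixture(scope="session")
def long_table(dataset):
    return dataset.long


@pytest.fixture(scope="session")
def time_aware(long_table):
    return build_time_aware(long_table)


@pytest.fixture(scope="session")
def time_agnostic(long_table):
    return build_time_agnostic(long_table)


@pytest.fixture(scope="session")
def sum_ubiquitous(time_aware, long_table):
    spec = PreprocessSpec("time_aware", "ubiquitous", "SUM")
    return preprocess_table(time_aware, spec, doc=long_table.doc)


def make_linear_problem(n=48, p=20, n_informative=3, noise_sd=0.0, seed=0):
    """Features plus a target exactly (or nearly) linear in a sparse subset."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    informative = rng.choice(p, size=n_informative, replace=False)
    beta[informative] = rng.uniform(1.0, 2.0, size=n_informative) * rng.choice([-1, 1], n_informative)
    y = X @ beta + rng.normal(0.0, noise_sd, size=n)
    return X, y, beta, np.sort(informative)
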