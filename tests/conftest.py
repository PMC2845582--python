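import numpy as np
import pytest

from pairpred import PlantedModel, gen_benchmark, gen_similarity


@pytest.fixture(scope="session")
def small_model():
    """Compact planted benchmark: 40 proteins, 4 families, 30 positives.

    Small enough that repeated cross-validation in CLI/evaluation tests
    runs in seconds.
    """
    return PlantedModel(n_proteins=40, n_families=4, n_positives=30, seed=7)


@pytest.fixture(scope="session")
def small_benchmark(small_model):
    return gen_benchmark(small_model)


@pytest.fixture(scope="session")
def small_similarity(small_model):
    return gen_similarity(small_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
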