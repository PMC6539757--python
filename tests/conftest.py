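"""Shared fixtures: the synthetic study set, trained models, fragment library.

The expensive objects (115-molecule set, the three fitted models, the
600+ fragment library) are session-scoped so the whole suite pays for
them once.
"""

import pytest

import fentaqsar as fq

STUDY_SEED = 1
STUDY_N = 115
STUDY_SIGMA = 0.2


@pytest.fixture(scope="session")
def dataset115():
    table, truth = fq.generate_dataset(n=STUDY_N, sigma=STUDY_SIGMA, seed=STUDY_SEED)
    return table, truth


@pytest.fixture(scope="session")
def noiseless115():
    table, truth = fq.generate_dataset(n=STUDY_N, sigma=0.0, seed=STUDY_SEED)
    return table, truth


@pytest.fixture(scope="session")
def split115(dataset115):
    table, _ = dataset115
    return fq.split_train_test(table, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def models(split115):
    table, trained = fq.train_models(split115, seed=STUDY_SEED)
    return table, trained


@pytest.fixture(scope="session")
def fragment_library():
    return fq.generate_fragment_library(n_min=600, seed=STUDY_SEED)


@pytest.fixture()
def small_table():
    table, _ = fq.generate_dataset(n=20, sigma=0.1, seed=7)
    return table
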