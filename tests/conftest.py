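import numpy as np
import pytest

from ssirisk.embeddings import train_embeddings
from ssirisk.synthetic_data import CohortSpec, CorpusSpec, generate_cohort, generate_corpus


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-record cohort at the default (study-like) conditions."""
    cohort, truth = generate_cohort(CohortSpec(n=2000, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def signal_cohort():
    """A 4,000-record cohort with 5% prevalence for model-fitting tests."""
    cohort, truth = generate_cohort(
        CohortSpec(n=4000, target_incidence=0.05, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_corpus():
    return generate_corpus(CorpusSpec(
        vocabulary_size=60, n_sentences=600,
        clusters=(("alpha", "beta"), ("gamma", "delta")), seed=3))


@pytest.fixture(scope="session")
def tiny_table(tiny_corpus):
    return train_embeddings(tiny_corpus, d=32, epochs=20, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
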