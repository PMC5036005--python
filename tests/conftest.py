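"""Shared fixtures: small deterministic references and cohorts."""
import numpy as np
import pytest

from apobecsig import simulate as sim


@pytest.fixture(scope="session")
def reference_10k() -> str:
    return sim.simulate_reference(10_000, gc_fraction=0.45, rng_seed=11)


@pytest.fixture(scope="session")
def small_cohort(reference_10k):
    """A 6-patient cohort with the default process mixture."""
    config = sim.CohortConfig(n_patients=6, mean_mutations=60,
                              reference_length=10_000, rng_seed=21)
    mutations, segments, metas, truth = sim.simulate_cohort(config,
                                                            reference_10k)
    return config, mutations, segments, metas, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
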