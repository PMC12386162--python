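import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ecoprs import (
    example_paths,
    harmonize,
    read_frequency_table,
    read_prevalence_table,
    read_scoring_file,
)


@pytest.fixture(scope="session")
def example_files():
    return example_paths()


@pytest.fixture(scope="session")
def scoring_model(example_files):
    return read_scoring_file(example_files[0])


@pytest.fixture(scope="session")
def frequency_table(example_files):
    return read_frequency_table(example_files[1])


@pytest.fixture(scope="session")
def prevalence_records(example_files):
    return read_prevalence_table(example_files[2])


@pytest.fixture(scope="session")
def harmonized(scoring_model, frequency_table):
    return harmonize(scoring_model, frequency_table)


@pytest.fixture(scope="session")
def prs_prevalence_vectors(harmonized, prevalence_records):
    """Aligned (PRS, prevalence, labels) vectors for the packaged example."""
    from ecoprs import all_population_prs

    model, freqs, _ = harmonized
    scores = all_population_prs(model, freqs)
    by_pop = {rec.population: rec.prevalence for rec in prevalence_records}
    x = np.array([s.prs for s in scores])
    y = np.array([by_pop[s.population] for s in scores])
    return x, y, [s.population for s in scores]
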