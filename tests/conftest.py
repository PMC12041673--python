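import pytest
from hypothesis import settings

from diatraj import (SimConfig, default_codebook, generate_cohort,
                     preprocess_cohort)

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def clean_records(codebook):
    """A small clean cohort run through the full cascade."""
    cohort, _ = generate_cohort(SimConfig(n_patients=400, seed=123))
    records, _ = preprocess_cohort(cohort, codebook, strict=True)
    return records


@pytest.fixture(scope="session")
def signal_records(codebook):
    """A larger cohort with the default planted risk structure."""
    cohort, truth = generate_cohort(SimConfig(n_patients=2500, seed=321))
    records, _ = preprocess_cohort(cohort, codebook, strict=True)
    return records, truth
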