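import pytest

from sarcosig import simulate_cohort, synthetic_signature_matrix
from sarcosig.synthetic import CohortSpec


@pytest.fixture(scope="session")
def synthetic_matrix():
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def default_cohort(synthetic_matrix):
    """The default 48-sample angiosarcoma-like synthetic cohort, seed 0."""
    spec = CohortSpec(seed=0)
    variants, meta, truth = simulate_cohort(spec, synthetic_matrix)
    return variants, meta, truth
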