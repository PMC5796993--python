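import numpy as np
import pytest

from apobecscan import (
    CohortSpec,
    ReferenceSequence,
    simulate_cohort,
    synthetic_cosmic_signatures,
)


@pytest.fixture(scope="session")
def signatures():
    return synthetic_cosmic_signatures()


@pytest.fixture(scope="session")
def small_ref():
    """A 5-kb seeded random reference for context tests."""
    from apobecscan import make_reference

    return make_reference(5000, seed=11)


@pytest.fixture(scope="session")
def bundle():
    """A mid-sized seeded cohort shared by the closed-loop tests."""
    return simulate_cohort(CohortSpec(n_samples=120, seed=7))


@pytest.fixture(scope="session")
def bundle_labels(bundle):
    """Enrichment classification of the shared cohort."""
    from apobecscan import accumulate_counts, classify_cohort

    counts = accumulate_counts(bundle.variants, bundle.reference)
    return classify_cohort(counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_reference(seq: str, name: str = "chr1") -> ReferenceSequence:
    return ReferenceSequence({name: seq})
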