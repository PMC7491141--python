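import pytest

from methmediate import SimParams, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized cohort under default study conditions (shared, read-only)."""
    return generate_cohort(SimParams(seed=11, n_samples=600, n_cpgs=300,
                                     n_snps=60))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for I/O round trips and cheap checks."""
    return generate_cohort(SimParams(seed=7, n_samples=100, n_cpgs=40,
                                     n_true_mediators=3, n_snps=30))
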