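import pytest

from annl.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Down-scaled default cohort with a known-network target (noise 0.01)."""
    return generate_cohort(
        CohortConfig(n_experimental=56, n_control=112, noise_sd=0.01, seed=11)
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free known-network cohort: targets exactly reproducible."""
    return generate_cohort(
        CohortConfig(n_experimental=56, n_control=112, noise_sd=0.0, seed=11)
    )
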