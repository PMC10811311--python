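import numpy as np
import pytest

from lungref import (
    PORCINE_REFERENCE,
    PORCINE_REFERENCE_LOWER,
    PORCINE_REFERENCE_UPPER,
    CohortSpec,
    generate_cohort,
)


@pytest.fixture
def reference_model():
    """The published exponential reference equation."""
    return PORCINE_REFERENCE


@pytest.fixture
def reference_bands():
    """(point, upper, lower) published model triple."""
    return PORCINE_REFERENCE, PORCINE_REFERENCE_UPPER, PORCINE_REFERENCE_LOWER


@pytest.fixture
def noiseless_cohort():
    """141 animals lying exactly on the reference curve."""
    return generate_cohort(CohortSpec(n=141, seed=7, noise_sigma_log10=0.0))


@pytest.fixture
def noisy_cohort():
    """A study-sized cohort (n=177) at the reference noise level."""
    return generate_cohort(CohortSpec(n=177, seed=11, noise_sigma_log10=0.068))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
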