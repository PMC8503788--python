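import pytest

from eshval import (
    CohortSpec,
    DeviceErrorModel,
    IDEAL_DEVICE,
    PAPER_LIKE_DEVICE,
    generate_cohort,
)


@pytest.fixture(scope="session")
def paper_like_cohort():
    """33-subject cohort with device bias 1.9 / noise SD 1.5 mmHg."""
    return generate_cohort(CohortSpec(seed=12345), PAPER_LIKE_DEVICE)


@pytest.fixture(scope="session")
def ideal_cohort():
    """Noiseless cohort: error-free device, noiseless observers, no drift."""
    spec = CohortSpec(seed=99, observer_noise_sd=0.0, within_session_drift_sd=0.0)
    return generate_cohort(spec, IDEAL_DEVICE)
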