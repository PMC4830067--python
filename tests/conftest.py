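import numpy as np
import pytest

from gaitdiff.synthetic import (
    CohortSpec,
    generate_marker_cohort,
    generate_waveform_cohort,
)


@pytest.fixture(scope="session")
def noiseless_marker_cohort():
    """Small noiseless marker-level cohort: rigid attachment and event
    construction are exact here."""
    spec = CohortSpec(
        seed=7,
        group_sizes={"OA_male": 2, "control_female": 2},
        marker_noise_sd_mm=0.0,
    )
    return generate_marker_cohort(spec)


@pytest.fixture(scope="session")
def noisy_marker_cohort():
    """Marker-level cohort with 1 mm marker noise."""
    spec = CohortSpec(
        seed=13,
        group_sizes={"OA_male": 3, "control_female": 3},
        marker_noise_sd_mm=1.0,
    )
    return generate_marker_cohort(spec)


@pytest.fixture(scope="session")
def null_waveform_cohort():
    """Waveform-level cohort with no group differences anywhere."""
    spec = CohortSpec(
        seed=11,
        group_sizes={"OA_male": 20, "OA_female": 20},
        effect_table={},
    )
    return generate_waveform_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
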