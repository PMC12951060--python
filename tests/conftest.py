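import logging

import numpy as np
import pytest

from pulseharm.synthetic import (
    AcquisitionConfig,
    CohortConfig,
    SubjectTruth,
    TEMPLATE_AMPLITUDES,
    TEMPLATE_PHASES,
)

logging.getLogger("pulseharm").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_subject(**overrides) -> SubjectTruth:
    """A deterministic subject built on the default template."""
    params = dict(
        subject_id="S001",
        sex="male",
        age=60.0,
        syntax_score=10.0,
        base_amplitudes=TEMPLATE_AMPLITUDES.copy(),
        base_phases=TEMPLATE_PHASES.copy(),
        asym_amplitudes=np.zeros(12),
        asym_phases=np.zeros(12),
        seed=7,
    )
    params.update(overrides)
    return SubjectTruth(**params)


@pytest.fixture
def clean_subject():
    """Subject with zero jitter, noise, drift and asymmetry."""
    return make_subject(
        amp_jitter_cv=0.0, phase_jitter_sd=0.0, period_cv=0.0,
        noise_sd=0.0, drift_amplitude=0.0,
    )


@pytest.fixture
def acq_60bpm():
    return AcquisitionConfig(sampling_rate=200.0, duration=60.0, heart_rate=60.0)


@pytest.fixture
def small_cohort_config():
    return CohortConfig(
        n_male=20, n_female=15, n_events_male=6, n_events_female=4, seed=3
    )
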