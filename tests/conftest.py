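import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from asapml.cohort import build_dataset
from asapml.preprocessing import normalize_unit_area
from asapml.synthetic import (
    EffectSpec,
    SimulationConfig,
    default_baseline_profile,
    generate_clinical_table,
    generate_spectrum_matrix,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_patients=283, seed=11)


@pytest.fixture(scope="session")
def planted_effect():
    return EffectSpec()  # 6 planted bins, effect 3, noise_cv 0.3


@pytest.fixture(scope="session")
def planted_cohort(sim_config, planted_effect):
    """Clinical table plus spectra with the default effect planted on HFD."""
    clinical = generate_clinical_table(sim_config)
    spectra = generate_spectrum_matrix(
        clinical, planted_effect, "hfd", sim_config
    )
    return clinical, spectra


@pytest.fixture(scope="session")
def planted_dataset(planted_cohort):
    clinical, spectra = planted_cohort
    return build_dataset(spectra, clinical, "hfd", subset="all", seed=0)


@pytest.fixture(scope="session")
def short_acq_config():
    """Acquisition timing shortened so per-test simulations stay fast."""
    return dataclasses.replace(
        SimulationConfig(seed=5),
        background_duration=9.0,
        sample_duration=9.0,
        gap_duration=3.6,
    )


@pytest.fixture(scope="session")
def unit_baseline(sim_config):
    return normalize_unit_area(default_baseline_profile(sim_config.bins))
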