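import numpy as np
import pytest

from lungmargin import RespiratoryConfig, simulate_cohort, simulate_fraction


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, drift-free, jitter-free fraction: modeler equals truth."""
    return RespiratoryConfig(
        corr_sys_mm=0.0,
        corr_rand_mm=0.0,
        pred_rand_mm=0.0,
        baseline_drift_mm_per_min=0.0,
        cycle_jitter_frac=0.0,
        duration_s=600.0,
    )


@pytest.fixture(scope="session")
def quiet_fraction(quiet_config):
    return simulate_fraction(quiet_config)


@pytest.fixture(scope="session")
def noisy_fraction():
    """Long fraction with unit correlation noise for recovery checks."""
    cfg = RespiratoryConfig(seed=17, corr_rand_mm=(1.0, 1.0, 1.0), duration_s=1800.0)
    return simulate_fraction(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Six patients, uncoupled noise: every fraction shares the injected SDs."""
    base = RespiratoryConfig(duration_s=900.0)
    return simulate_cohort(
        n_patients=6, base_config=base, seed=5, noise_amplitude_coupling=0.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
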