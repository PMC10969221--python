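import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stageshift import RunConfig, calibrate_intercepts, run_baseline
from stageshift import config as config_mod

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

MASTER_SEED = 1
CALIBRATION_STREAM = 987654321


@pytest.fixture(scope="session")
def default_config():
    return config_mod.load_config()


@pytest.fixture(scope="session")
def cohort_spec(default_config):
    return config_mod.cohort_spec_from_config(default_config)


@pytest.fixture(scope="session")
def raw_coeffs(default_config):
    return config_mod.coefficient_set_from_config(default_config)


@pytest.fixture(scope="session")
def calibrated_coeffs(default_config, cohort_spec, raw_coeffs):
    return calibrate_intercepts(
        cohort_spec,
        raw_coeffs,
        config_mod.baseline_distribution(default_config),
        n_calib=int(default_config["model"]["calibration_n"]),
        seed=(MASTER_SEED, CALIBRATION_STREAM),
    )


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(n_realizations=20, n_per_realization=1000, master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def baseline_result(cohort_spec, calibrated_coeffs, run_config):
    return run_baseline(cohort_spec, calibrated_coeffs, run_config)
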