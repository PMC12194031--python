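import dataclasses

import numpy as np
import pytest

import ckdap_cea as cc


@pytest.fixture
def default_cfg():
    return cc.default_config()


@pytest.fixture
def small_cfg():
    """Reduced problem size for fast end-to-end runs."""
    cfg = cc.default_config()
    cfg.cohort = dataclasses.replace(cfg.cohort, n_per_arm=200, seed=7)
    cfg.schedule = dataclasses.replace(cfg.schedule, horizon_years=20)
    return cfg


@pytest.fixture(scope="session")
def calibration_records():
    """Default-calibration cohort at the size the response check uses."""
    params = cc.CohortGenParams(n_per_arm=2000, seed=1)
    return cc.generate_cohort(params)


@pytest.fixture(scope="session")
def base_small_session():
    cfg = cc.default_config()
    cfg.cohort = dataclasses.replace(cfg.cohort, n_per_arm=200, seed=7)
    cfg.schedule = dataclasses.replace(cfg.schedule, horizon_years=20)
    return cc.run_base_case(cfg)


@pytest.fixture
def surv_inputs(default_cfg):
    return default_cfg.survival_inputs()


@pytest.fixture
def entry_moderate():
    """Entry distribution fully in the moderate state."""
    return np.array([0.0, 0.0, 1.0, 0.0, 0.0])
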