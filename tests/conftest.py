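import numpy as np
import pytest

from asdcem.config import ModelConfig
from asdcem.synthetic_data import make_gompertz_lifetable


@pytest.fixture(scope="session")
def table():
    """Synthetic Gompertz lifetable used by every offline test."""
    return make_gompertz_lifetable()


@pytest.fixture()
def config_small():
    """Basecase config with a small cohort for fast tests."""
    cfg = ModelConfig.default()
    cfg.engine.n_individuals = 2_000
    cfg.engine.seed = 732019
    return cfg


@pytest.fixture()
def config_large():
    cfg = ModelConfig.default()
    cfg.engine.n_individuals = 100_000
    cfg.engine.seed = 732019
    return cfg


@pytest.fixture()
def zero_mortality_table():
    """qx = 0 everywhere except the absorbing cap at age 100."""
    from asdcem.life_tables import LifeTable

    ages = np.arange(101)
    qx = np.zeros(101)
    qx[-1] = 1.0
    return LifeTable(age=ages, qx_male=qx.copy(), qx_female=qx.copy())


def deterministic_overrides():
    """Zero out every sampling sd so trajectories are deterministic."""
    return {
        "natural_history.baseline_composite_sd": 0.0,
        "intervention.comm_change_soc.sd": 0.0,
        "intervention.comm_change_cb.sd": 0.0,
        "intervention.soc_change_both.sd": 0.0,
        "intervention.dls_change_both.sd": 0.0,
        "natural_history.monthly_change": [
            {"age_lo": 2.0, "age_hi": 4.0, "mean": 0.05, "sd": 0.0},
            {"age_lo": 4.0, "age_hi": 5.0, "mean": 0.14, "sd": 0.0},
            {"age_lo": 5.0, "age_hi": 6.0, "mean": 0.14, "sd": 0.0},
            {"age_lo": 6.0, "age_hi": 7.0, "mean": 0.14, "sd": 0.0},
        ],
    }
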