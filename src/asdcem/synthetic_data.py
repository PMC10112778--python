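"""Synthetic inputs: Gompertz lifetable and fixture configurations.

The real 2017 US period lifetable cannot be shipped; a parametric Gompertz
lifetable stands in for it so the whole package builds and tests offline.
To run the external-data validation targets, transcribe the published
lifetable into the CSV schema ``age,qx_male,qx_female`` (one row per single
year of age 0..100, '.' decimal separator) and point ``lifetable_path`` at
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np

from .life_tables import LifeTable

__all__ = ["GompertzParams", "make_gompertz_lifetable", "make_fixture_config"]

#: Fixed fixture seed committed to the repo.
FIXTURE_SEED = 73_2019


@dataclass
class GompertzParams:
    alpha: float = 2.0e-5  # baseline annual hazard (female)
    beta_g: float = 0.095  # log-hazard slope per year of age
    max_age: int = 100
    sex_hazard_ratio: float = 1.6  # male : female

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta_g <= 0:
            raise ValueError("alpha and beta_g must be positive")
        if self.sex_hazard_ratio <= 0:
            raise ValueError("sex_hazard_ratio must be positive")


def make_gompertz_lifetable(params: Optional[GompertzParams] = None) -> LifeTable:
    """Build a lifetable with qx_sex(a) = 1 - exp(-h_sex(a)).

    h_female(a) = alpha * exp(beta_g * a); male hazard is sex_hazard_ratio
    times the female hazard.  The row at max_age is forced to qx = 1.
    """
    params = params if params is not None else GompertzParams()
    ages = np.arange(params.max_age + 1)
    h_female = params.alpha * np.exp(params.beta_g * ages)
    h_male = params.sex_hazard_ratio * h_female
    qx_female = -np.expm1(-h_female)
    qx_male = -np.expm1(-h_male)
    if np.any(qx_male[:60] >= 1.0) or np.any(qx_female[:60] >= 1.0):
        raise ValueError(
            "implausible Gompertz parameters: qx reaches 1 before age 60"
        )
    qx_female[-1] = 1.0
    qx_male[-1] = 1.0
    return LifeTable(age=ages, qx_male=qx_male, qx_female=np.clip(qx_female, 0, 1))


def make_fixture_config(
    overrides: Optional[dict[str, Any]] = None,
    lifetable_path: Optional[str | Path] = None,
    path: Optional[str | Path] = None,
    n: int = 2_000,
    seed: int = FIXTURE_SEED,
):
    """Complete basecase config with a small n and fixed seed for tests.

    Optionally writes the YAML to ``path``.  An empty override set
    reproduces the documented defaults exactly.
    """
    from .config import ModelConfig

    cfg = ModelConfig.default()
    cfg.engine.n_individuals = n
    cfg.engine.seed = seed
    if lifetable_path is not None:
        cfg.lifetable_path = str(lifetable_path)
    if overrides:
        cfg = cfg.with_overrides(overrides)
    if path is not None:
        cfg.to_yaml(path)
    return cfg
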