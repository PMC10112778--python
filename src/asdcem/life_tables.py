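"""Period lifetables and SMR-adjusted, sex-mixed monthly mortality.

A :class:`LifeTable` holds sex-specific annual death probabilities (``qx``)
by single year of age.  For the simulated cohort the annual probabilities are
converted to monthly hazard rates, multiplied by sex-specific standardized
mortality ratios (SMRs), mixed at the cohort's male fraction at the *rate*
level, and converted back to a monthly probability:

    p = 1 - exp(-[f_m * SMR_m * r_m + (1 - f_m) * SMR_f * r_f]),
    r_s = -ln(1 - qx_s(floor(age))) / 12

Annual ``qx`` is held constant within each year of age (step function).  The
row at ``max_age`` is an absorbing cap: everyone still alive dies there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "MortalityParams",
    "LifeTableError",
    "load_lifetable",
    "monthly_asd_death_probability",
    "monthly_death_probabilities",
    "life_expectancy_from_age2",
]

LIFETABLE_COLUMNS = ("age", "qx_male", "qx_female")


class LifeTableError(ValueError):
    """Raised for malformed lifetable input."""


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific annual death probabilities by single year of age."""

    age: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=int)
        qm = np.asarray(self.qx_male, dtype=float)
        qf = np.asarray(self.qx_female, dtype=float)
        if not (len(age) == len(qm) == len(qf)):
            raise LifeTableError("age/qx columns have unequal lengths")
        if len(age) == 0:
            raise LifeTableError("empty lifetable")
        if age[0] != 0 or np.any(np.diff(age) != 1):
            raise LifeTableError("ages must be consecutive integers starting at 0")
        for name, q in (("qx_male", qm), ("qx_female", qf)):
            if np.any(~np.isfinite(q)) or np.any(q < 0.0) or np.any(q > 1.0):
                raise LifeTableError(f"{name} values must lie in [0, 1]")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "qx_male", qm)
        object.__setattr__(self, "qx_female", qf)

    @property
    def max_age(self) -> int:
        return int(self.age[-1])

    def qx(self, sex: str, year_age: int) -> float:
        """Annual death probability at integer age; 1 at/above the cap."""
        if year_age < 0:
            raise LifeTableError(f"negative age {year_age}")
        if year_age >= self.max_age:
            return 1.0
        q = self.qx_male if sex == "male" else self.qx_female
        return float(q[year_age])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.age, "qx_male": self.qx_male, "qx_female": self.qx_female}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class MortalityParams:
    """SMRs and sex mix applied on top of the general-population lifetable."""

    smr_male: float = 2.49
    smr_female: float = 1.88
    fraction_male: float = 0.782
    max_age: int = 100

    def __post_init__(self) -> None:
        if self.smr_male <= 0 or self.smr_female <= 0:
            raise ValueError("SMRs must be positive")
        if not 0.0 <= self.fraction_male <= 1.0:
            raise ValueError("fraction_male must lie in [0, 1]")


def load_lifetable(
    path: str | Path, schema: Sequence[str] = LIFETABLE_COLUMNS
) -> LifeTable:
    """Read a lifetable CSV with columns ``age,qx_male,qx_female``."""
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise LifeTableError(f"lifetable CSV missing columns: {missing}")
    age_col, male_col, female_col = schema
    return LifeTable(
        age=df[age_col].to_numpy(),
        qx_male=df[male_col].to_numpy(dtype=float),
        qx_female=df[female_col].to_numpy(dtype=float),
    )


def _annual_to_monthly_rate(qx: np.ndarray | float) -> np.ndarray | float:
    """-ln(1 - qx)/12, with qx = 1 mapping to an infinite rate."""
    qx = np.asarray(qx, dtype=float)
    with np.errstate(divide="ignore"):
        rate = -np.log1p(-qx) / 12.0
    return rate


def _mixed_monthly_rate(
    table: LifeTable, params: MortalityParams, year_age: np.ndarray | int
) -> np.ndarray:
    year_age = np.asarray(year_age, dtype=int)
    capped = year_age >= min(table.max_age, params.max_age)
    idx = np.clip(year_age, 0, table.max_age)
    qm = np.where(capped, 1.0, table.qx_male[np.minimum(idx, len(table.age) - 1)])
    qf = np.where(capped, 1.0, table.qx_female[np.minimum(idx, len(table.age) - 1)])
    f = params.fraction_male
    rate = f * params.smr_male * _annual_to_monthly_rate(qm) + (
        1.0 - f
    ) * params.smr_female * _annual_to_monthly_rate(qf)
    return rate


def monthly_asd_death_probability(
    table: LifeTable, params: MortalityParams, age: float
) -> float:
    """SMR-adjusted, sex-mixed monthly death probability at a given age.

    Returns 1 at or beyond ``max_age`` (absorbing cap).
    """
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    cap = min(table.max_age, params.max_age)
    if age > max(table.max_age, params.max_age):
        raise ValueError(f"age {age} beyond lifetable cap {cap}")
    if age >= cap:
        return 1.0
    rate = _mixed_monthly_rate(table, params, int(np.floor(age)))
    return float(-np.expm1(-rate))


def monthly_death_probabilities(
    table: LifeTable, params: MortalityParams, entry_age: float = 2.0
) -> np.ndarray:
    """Monthly death probabilities for months since entry, up to the cap.

    Element ``m`` is the probability of dying during the month starting at age
    ``entry_age + m/12``; the array covers ages ``[entry_age, max_age)``.
    Death is forced at the cap, which is *not* included here.
    """
    cap = min(table.max_age, params.max_age)
    n_months = int(round((cap - entry_age) * 12))
    if n_months <= 0:
        return np.zeros(0)
    ages = entry_age + np.arange(n_months) / 12.0
    year_ages = np.floor(ages).astype(int)
    rates = _mixed_monthly_rate(table, params, year_ages)
    return -np.expm1(-rates)


def life_expectancy_from_age2(
    table: LifeTable, params: MortalityParams, entry_age: float = 2.0
) -> float:
    """Expected age at death for the SMR-adjusted cohort entering at age 2.

    Deterministic monthly survival summation: E[age] = entry + E[D]/12 where
    D is the month of death and survivors of every tabulated month die at the
    cap.  Serves as the analytic oracle for the simulated cohort's mean age
    at death.
    """
    p = monthly_death_probabilities(table, params, entry_age)
    survival = np.cumprod(1.0 - p)  # S(m+1) for m = 0..M-1
    return float(entry_age + survival.sum() / 12.0)
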