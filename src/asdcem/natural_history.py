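"""Baseline cohort generation and monthly adaptive-behavior trajectories.

Individuals enter at age 2 with a composite adaptive-behavior (VABS-3) score
drawn from Normal(71.8, 11.8); all three subscales (communication, daily
living skills, socialization) start at that value.  From ages 2 to 7 the
scores grow by age-band-specific monthly increments; from age 7 on they are
frozen.  At age 18 each individual is assigned one of three permanent adult
strata based on the composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GrowthBand",
    "CohortParams",
    "NaturalHistoryParams",
    "IndividualState",
    "STRATA",
    "draw_baseline",
    "draw_baseline_scores",
    "growth_band_for_age",
    "natural_history_increment",
    "adult_stratum_for_composite",
    "assign_adult_stratum",
]

#: Adult stratum labels, in engine code order 0/1/2.
STRATA = ("gt85", "70to85", "lt70")


@dataclass
class GrowthBand:
    """Monthly composite change distribution over an age band [lo, hi)."""

    age_lo: float
    age_hi: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("growth sd must be nonnegative")
        if self.age_hi <= self.age_lo:
            raise ValueError("empty growth band")


@dataclass
class CohortParams:
    entry_age: float = 2.0
    fraction_male: float = 0.782
    nviq: float = 88.1
    ados_css: float = 16.7

    def __post_init__(self) -> None:
        if self.entry_age < 0:
            raise ValueError("entry_age must be nonnegative")
        if self.nviq <= 0 or self.ados_css <= 0:
            raise ValueError("cohort scores must be positive")


def _default_bands() -> list[GrowthBand]:
    return [
        GrowthBand(2.0, 4.0, 0.05, 0.01),
        GrowthBand(4.0, 5.0, 0.14, 0.02),
        GrowthBand(5.0, 6.0, 0.14, 0.02),
        GrowthBand(6.0, 7.0, 0.14, 0.02),
    ]


@dataclass
class NaturalHistoryParams:
    baseline_composite_mean: float = 71.8
    baseline_composite_sd: float = 11.8
    monthly_change: list[GrowthBand] = field(default_factory=_default_bands)
    growth_stop_age: float = 7.0
    vabs_floor: float = 20.0
    vabs_ceiling: float = 140.0
    #: one growth-rate draw per individual per band, reused monthly (default);
    #: False redraws the increment every month.
    per_individual_rates: bool = True

    def __post_init__(self) -> None:
        if self.baseline_composite_sd < 0:
            raise ValueError("baseline sd must be nonnegative")
        if self.vabs_floor >= self.vabs_ceiling:
            raise ValueError("vabs_floor must be below vabs_ceiling")
        self.monthly_change = [
            b if isinstance(b, GrowthBand) else GrowthBand(**b)
            for b in self.monthly_change
        ]


@dataclass
class IndividualState:
    """One simulated person's state and accrued outcome ledger."""

    id: int
    age: float
    alive: bool = True
    vabs_comm: float = 0.0
    vabs_dls: float = 0.0
    vabs_soc: float = 0.0
    adult_stratum: str = "unassigned"
    qaly_undiscounted: float = 0.0
    qaly_discounted: float = 0.0
    cost_societal_undiscounted: float = 0.0
    cost_societal_discounted: float = 0.0
    cost_payer_undiscounted: float = 0.0
    cost_payer_discounted: float = 0.0

    @property
    def composite(self) -> float:
        """Arithmetic mean of the three subscale scores."""
        return (self.vabs_comm + self.vabs_dls + self.vabs_soc) / 3.0


def draw_baseline_scores(
    params: NaturalHistoryParams, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Vector of n baseline composite draws, clamped to [floor, ceiling]."""
    draws = params.baseline_composite_mean + params.baseline_composite_sd * (
        rng.standard_normal(n)
    )
    return np.clip(draws, params.vabs_floor, params.vabs_ceiling)


def draw_baseline(
    params: NaturalHistoryParams,
    cohort: CohortParams,
    rng: np.random.Generator,
    id: int = 0,
) -> IndividualState:
    """Draw one individual's baseline state; subscales equal the composite draw."""
    score = float(draw_baseline_scores(params, rng, 1)[0])
    return IndividualState(
        id=id,
        age=cohort.entry_age,
        vabs_comm=score,
        vabs_dls=score,
        vabs_soc=score,
    )


def growth_band_for_age(
    params: NaturalHistoryParams, age: float
) -> Optional[GrowthBand]:
    """Band covering ``age``, or None from growth_stop_age on."""
    if age >= params.growth_stop_age:
        return None
    for band in params.monthly_change:
        if band.age_lo <= age < band.age_hi:
            return band
    raise ValueError(f"age {age} below modelled entry (bands start at "
                     f"{params.monthly_change[0].age_lo})")


def natural_history_increment(
    params: NaturalHistoryParams, age: float, rng: np.random.Generator
) -> float:
    """One monthly composite increment draw; 0 from growth_stop_age on.

    The same increment is added to all three subscales that month.
    """
    band = growth_band_for_age(params, age)
    if band is None:
        return 0.0
    return float(rng.normal(band.mean, band.sd))


def adult_stratum_for_composite(composite: float) -> str:
    """Stratum label: >85 high, [70, 85] middle (both bounds), <70 low."""
    if composite > 85.0:
        return "gt85"
    if composite >= 70.0:
        return "70to85"
    return "lt70"


def assign_adult_stratum(state: IndividualState) -> str:
    """Assign the permanent adult stratum at the first monthly step >= 18."""
    if state.adult_stratum != "unassigned":
        raise RuntimeError("adult stratum already assigned; it is immutable")
    if state.age < 18.0:
        raise RuntimeError("adult stratum is assigned at age 18, not before")
    state.adult_stratum = adult_stratum_for_composite(state.composite)
    return state.adult_stratum
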