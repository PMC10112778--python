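"""Annual and monthly cost accrual by age, adult stratum, and perspective.

Children (ages 2-17) carry flat annual costs; adults carry itemized annual
components whose total at defaults is $56,559 (2019 USD).  Only the
individual-productivity-loss component varies by adult stratum: it scales
with (1 - labor-force participation), normalized so the middle stratum
(LFP 40%) reproduces the published $12,047.  The payer perspective includes
the child healthcare share and the adult medical-services component only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .natural_history import STRATA

if TYPE_CHECKING:  # pragma: no cover
    from .natural_history import IndividualState

__all__ = ["CostParams", "annual_cost", "monthly_cost", "adult_annual_costs"]

SOCIETAL = "societal"
PAYER = "payer"
_PERSPECTIVES = (SOCIETAL, PAYER)


def _default_lfp() -> dict[str, float]:
    return {"gt85": 0.60, "70to85": 0.40, "lt70": 0.20}


@dataclass
class CostParams:
    child_societal_annual: float = 19_199.0
    child_payer_annual: float = 3_395.0
    adult_accommodation: float = 20_322.0
    adult_employment_support: float = 396.0
    adult_medical: float = 15_264.0
    adult_nonmedical: float = 6_399.0
    adult_caregiver_productivity: float = 2_131.0
    adult_individual_productivity: float = 12_047.0
    lfp_by_stratum: dict[str, float] = field(default_factory=_default_lfp)
    lfp_reference: float = 0.40
    adjust_caregiver_productivity: bool = False
    #: divides the five non-individual-productivity adult components
    #: (reduced-adult-cost scenario uses 3).
    adult_cost_divisor: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "child_societal_annual",
            "child_payer_annual",
            "adult_accommodation",
            "adult_employment_support",
            "adult_medical",
            "adult_nonmedical",
            "adult_caregiver_productivity",
            "adult_individual_productivity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for stratum, lfp in self.lfp_by_stratum.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r}")
            if not 0.0 <= lfp <= 1.0:
                raise ValueError("LFP values must lie in [0, 1]")
        if not 0.0 <= self.lfp_reference < 1.0:
            raise ValueError("lfp_reference must lie in [0, 1)")
        if self.adult_cost_divisor <= 0:
            raise ValueError("adult_cost_divisor must be positive")

    def productivity_scale(self, stratum: str) -> float:
        """(1 - LFP) / (1 - reference LFP) scaling of productivity loss."""
        return (1.0 - self.lfp_by_stratum[stratum]) / (1.0 - self.lfp_reference)


def adult_annual_costs(params: CostParams, stratum: str) -> dict[str, float]:
    """Itemized annual adult costs for one stratum (societal components)."""
    scale = params.productivity_scale(stratum)
    div = params.adult_cost_divisor
    caregiver = params.adult_caregiver_productivity * (
        scale if params.adjust_caregiver_productivity else 1.0
    )
    return {
        "accommodation": params.adult_accommodation / div,
        "employment_support": params.adult_employment_support / div,
        "medical": params.adult_medical / div,
        "nonmedical": params.adult_nonmedical / div,
        "caregiver_productivity": caregiver / div,
        "individual_productivity": params.adult_individual_productivity * scale,
    }


def annual_cost(
    params: CostParams,
    age: float,
    stratum: str | None,
    perspective: str,
) -> float:
    """Annual cost (2019 USD/yr) for an individual of given age and stratum."""
    if perspective not in _PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    if age < 18.0:
        if perspective == SOCIETAL:
            return params.child_societal_annual
        return params.child_payer_annual
    if stratum is None or stratum == "unassigned":
        raise RuntimeError("adult cost requires an assigned stratum")
    if perspective == PAYER:
        return params.adult_medical / params.adult_cost_divisor
    return sum(adult_annual_costs(params, stratum).values())


def monthly_cost(
    params: CostParams,
    state: "IndividualState",
    perspective: str,
    discount_rate: float,
    months_since_entry: int,
) -> tuple[float, float]:
    """(undiscounted, discounted) monthly cost for one lived month."""
    if not state.alive:
        return 0.0, 0.0
    stratum = state.adult_stratum if state.age >= 18.0 else None
    undisc = annual_cost(params, state.age, stratum, perspective) / 12.0
    disc = undisc * (1.0 + discount_rate) ** (-months_since_entry / 12.0)
    return undisc, disc
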