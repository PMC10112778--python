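"""Deterministic sensitivity analyses and the 5-year budget impact.

Every analysis here is a pure config transform: overrides are applied via
``ModelConfig.with_overrides`` and the paired engine is rerun under the same
seed, so results are deterministic given the seed and independent of call
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import engine as eng
from .life_tables import LifeTable

if TYPE_CHECKING:  # pragma: no cover
    from .config import ModelConfig

__all__ = [
    "SensitivitySpec",
    "BIAParams",
    "SCENARIOS",
    "default_tornado_specs",
    "tornado",
    "two_way_grid",
    "scenario",
    "budget_impact",
]


@dataclass
class SensitivitySpec:
    """One-way sensitivity range for a dotted config key."""

    parameter: str
    low: float
    high: float
    base: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.parameter}: require low <= base <= high, "
                f"got {self.low}/{self.base}/{self.high}"
            )


@dataclass
class BIAParams:
    """Budget-impact inputs: eligible US children ages 2-7, payer view."""

    eligible_population: int = 247_000
    uptake: float = 1.0
    horizon_years: int = 5
    perspective: str = "payer"

    def __post_init__(self) -> None:
        if not 0.0 <= self.uptake <= 1.0:
            raise ValueError("uptake must lie in [0, 1]")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")


def default_tornado_specs() -> list[SensitivitySpec]:
    """Shipped one-way ranges.

    Only the utility-mapping communication coefficient extremes (0.0019 /
    0.0074) are published; the remaining ranges are reconstructed plausible
    spans around the basecase and are meant to be edited via a spec file.
    """
    return [
        SensitivitySpec("intervention.cost_infusion", 8_000, 45_000, 15_000),
        SensitivitySpec("intervention.comm_change_cb.mean", 1.0, 6.0, 3.0),
        SensitivitySpec("qol.beta_comm", 0.0019, 0.0074, 0.0037),
        SensitivitySpec("intervention.cost_ae_mild", 0.0, 10_500, 2_100.0),
        SensitivitySpec("intervention.cost_ae_severe", 0.0, 34_713, 11_571.0),
        SensitivitySpec("intervention.p_severe", 0.0, 0.10, 0.034),
        SensitivitySpec("intervention.p_mild_moderate", 0.0, 0.20, 0.092),
        SensitivitySpec("engine.discount_rate", 0.0, 0.05, 0.03),
    ]


def _paired_icer(
    config: "ModelConfig", table: LifeTable, perspective: str
) -> tuple[Optional[float], Optional[str], eng.CEResult]:
    soc, cb = eng.run_pair(config, table=table)
    ce = eng.compare(soc, cb, perspective=perspective)
    return ce.icer, ce.dominance, ce


def _perspective(config: "ModelConfig") -> str:
    p = config.engine.perspective
    return "societal" if p == "both" else p


def tornado(
    config: "ModelConfig",
    specs: Sequence[SensitivitySpec],
    table: Optional[LifeTable] = None,
) -> pd.DataFrame:
    """One-way sensitivity table, widest ICER span first.

    Each parameter is set to its low and high value in turn (all else at
    base) and the paired simulation rerun under the identical seed.
    """
    table = eng._resolve_table(config, table)
    perspective = _perspective(config)
    rows = []
    for spec in specs:
        icers = {}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            cfg = config.with_overrides({spec.parameter: value})
            icers[bound], dom, _ = _paired_icer(cfg, table, perspective)
            if icers[bound] is None:
                icers[bound] = float("nan") if dom is None else float("inf")
        lo, hi = sorted([icers["low"], icers["high"]])
        rows.append(
            {
                "parameter": spec.parameter,
                "value_low": spec.low,
                "value_high": spec.high,
                "icer_at_low": icers["low"],
                "icer_at_high": icers["high"],
                "icer_min": lo,
                "icer_max": hi,
                "span": hi - lo,
            }
        )
    df = pd.DataFrame(rows).sort_values("span", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def two_way_grid(
    config: "ModelConfig",
    efficacy_values: Sequence[float],
    cost_values: Sequence[float],
    table: Optional[LifeTable] = None,
) -> pd.DataFrame:
    """ICER grid over CB efficacy (rows) x CB cost (columns).

    The SOC arm does not depend on CB-only parameters and is run once.
    """
    if len(efficacy_values) == 0 or len(cost_values) == 0:
        raise ValueError("efficacy and cost grids must be nonempty")
    table = eng._resolve_table(config, table)
    perspective = _perspective(config)
    soc = eng.run_cohort(config, "soc", table=table)
    rows = []
    for efficacy in efficacy_values:
        for cost in cost_values:
            cfg = config.with_overrides(
                {
                    "intervention.comm_change_cb.mean": float(efficacy),
                    "intervention.cost_infusion": float(cost),
                }
            )
            cb = eng.run_cohort(cfg, "cb", table=table)
            ce = eng.compare(soc, cb, perspective=perspective)
            rows.append(
                {
                    "efficacy": float(efficacy),
                    "cost": float(cost),
                    "delta_cost": ce.delta_cost,
                    "delta_qaly": ce.delta_qaly,
                    "icer": ce.icer if ce.icer is not None else float("nan"),
                    "dominance": ce.dominance or "",
                    "threshold_class": ce.threshold_class,
                }
            )
    return pd.DataFrame(rows)


#: Named scenarios as documented, editable override sets.
SCENARIOS: dict[str, dict[str, Any]] = {
    "best_case": {
        "intervention.cost_infusion": 8_000.0,
        "intervention.comm_change_cb.mean": 6.0,
        "qol.beta_comm": 0.0074,
        # productivity spread widened to 60 points across strata
        "costs.lfp_by_stratum.gt85": 0.80,
        "costs.lfp_by_stratum.70to85": 0.40,
        "costs.lfp_by_stratum.lt70": 0.20,
    },
    "worst_case": {
        "intervention.cost_infusion": 45_000.0,
        "intervention.comm_change_cb.mean": 1.0,
        "qol.beta_comm": 0.0019,
        # productivity spread collapsed: all strata at the reference LFP
        "costs.lfp_by_stratum.gt85": 0.40,
        "costs.lfp_by_stratum.70to85": 0.40,
        "costs.lfp_by_stratum.lt70": 0.40,
    },
    # only CB communication draws at or above the minimal clinically
    # important difference count; all others are zeroed
    "mcid_only": {"intervention.mcid_threshold": 2.0},
    "payer": {"engine.perspective": "payer"},
    "reduced_adult_costs": {"costs.adult_cost_divisor": 3.0},
    # efficacy 0: the CB communication draw equals the SOC draw exactly
    "zero_efficacy": {
        "intervention.comm_change_cb.mean": 0.1,
        "intervention.comm_change_cb.sd": 7.3,
    },
}


def scenario(
    config: "ModelConfig",
    name: str,
    table: Optional[LifeTable] = None,
) -> eng.CEResult:
    """Run a named scenario and return its paired cost-effectiveness result."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    cfg = config.with_overrides(SCENARIOS[name])
    table = eng._resolve_table(cfg, table)
    perspective = _perspective(cfg)
    soc, cb = eng.run_pair(cfg, table=table)
    return eng.compare(soc, cb, perspective=perspective)


def budget_impact(
    config: "ModelConfig",
    bia: Optional[BIAParams] = None,
    table: Optional[LifeTable] = None,
) -> dict[str, float]:
    """Total 5-year undiscounted incremental payer cost of offering CB.

    The per-person increment comes from a paired cohort run (child payer
    costs cancel under common random numbers since mortality is strategy
    independent; the remainder is the infusion plus adverse-event costs),
    scaled by the eligible population and uptake.  Exactly linear in both.
    """
    bia = bia if bia is not None else config.bia
    table = eng._resolve_table(config, table)
    soc, cb = eng.run_pair(config, table=table)
    diff = (
        cb.ledger.payer_cost_5yr_undiscounted - soc.ledger.payer_cost_5yr_undiscounted
    )
    per_person = float(np.mean(diff))
    total = per_person * bia.eligible_population * bia.uptake
    return {
        "per_person_increment": per_person,
        "eligible_population": float(bia.eligible_population),
        "uptake": float(bia.uptake),
        "total": total,
        "total_billion": total / 1e9,
    }
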