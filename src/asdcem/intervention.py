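"""Trial-derived six-month subscale changes, adverse events, and costs.

Both arms draw six-month changes in the socialization and daily-living
subscales from the same distributions.  The communication change differs:
Normal(0.1, 7.3) under standard of care (SOC) and Normal(3.0, 7.9) under the
cord-blood (CB) arm.  A severe adverse event (CB only, first month) stops the
therapy: the CB communication draw is replaced by the SOC one.  Changes are
applied in six equal monthly installments during months 0-5.

For common-random-numbers pairing the arm draws share a standard-normal
variate z; the realized change is ``mean_arm + sd_arm * z`` so that arms with
identical parameters are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "NormalParams",
    "InterventionParams",
    "SOC",
    "CB",
    "draw_six_month_changes",
    "draw_adverse_event",
    "expected_first_month_excess_cost",
]

SOC = "soc"
CB = "cb"
_STRATEGIES = (SOC, CB)

#: QALY-day denominator for adverse-event utility decrements.
DAYS_PER_YEAR = 365.25


@dataclass
class NormalParams:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class InterventionParams:
    comm_change_soc: NormalParams = field(default_factory=lambda: NormalParams(0.1, 7.3))
    comm_change_cb: NormalParams = field(default_factory=lambda: NormalParams(3.0, 7.9))
    soc_change_both: NormalParams = field(default_factory=lambda: NormalParams(3.2, 9.2))
    dls_change_both: NormalParams = field(default_factory=lambda: NormalParams(2.8, 6.7))
    p_mild_moderate: float = 0.092
    p_severe: float = 0.034
    mild_decrement_days: float = 0.25
    severe_decrement_days: float = 7.0
    cost_infusion: float = 15_000.0
    cost_ae_mild: float = 2_100.0
    cost_ae_severe: float = 11_571.0
    effect_window_months: int = 6
    #: minimal-clinically-important-difference truncation of realized CB
    #: communication draws (draw if draw >= threshold else 0); None disables.
    mcid_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("p_mild_moderate", "p_severe"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_mild_moderate + self.p_severe > 1.0:
            raise ValueError("adverse-event probabilities exceed 1")
        for name in ("cost_infusion", "cost_ae_mild", "cost_ae_severe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _check_strategy(strategy: str) -> None:
    if strategy not in _STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {_STRATEGIES}")


def realized_comm_change(
    params: InterventionParams,
    strategy: str,
    severe_ae: np.ndarray | bool,
    z: np.ndarray | float,
) -> np.ndarray:
    """Six-month communication change from a shared standard-normal variate.

    Severe adverse events (CB only) replace the treatment draw with the SOC
    draw built from the *same* z.  The MCID truncation, when configured,
    zeroes non-severe CB draws below the threshold.
    """
    _check_strategy(strategy)
    z = np.asarray(z, dtype=float)
    severe = np.asarray(severe_ae, dtype=bool)
    if strategy == SOC and np.any(severe):
        raise ValueError("severe adverse events cannot occur under SOC")
    soc_draw = params.comm_change_soc.mean + params.comm_change_soc.sd * z
    if strategy == SOC:
        return soc_draw
    cb_draw = params.comm_change_cb.mean + params.comm_change_cb.sd * z
    if params.mcid_threshold is not None:
        cb_draw = np.where(cb_draw >= params.mcid_threshold, cb_draw, 0.0)
    return np.where(severe, soc_draw, cb_draw)


def draw_six_month_changes(
    params: InterventionParams,
    strategy: str,
    severe_ae: bool,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Draw (Dcomm, Dsoc, Ddls) six-month subscale changes for one person."""
    _check_strategy(strategy)
    d_comm = float(
        realized_comm_change(params, strategy, severe_ae, rng.standard_normal())
    )
    d_soc = float(rng.normal(params.soc_change_both.mean, params.soc_change_both.sd))
    d_dls = float(rng.normal(params.dls_change_both.mean, params.dls_change_both.sd))
    return d_comm, d_soc, d_dls


def classify_adverse_event(
    params: InterventionParams, strategy: str, u: np.ndarray | float
) -> np.ndarray:
    """Map uniforms to event codes 0 = none, 1 = mild/moderate, 2 = severe."""
    _check_strategy(strategy)
    u = np.asarray(u, dtype=float)
    if strategy == SOC:
        return np.zeros(u.shape, dtype=np.int8)
    severe = u < params.p_severe
    mild = (~severe) & (u < params.p_severe + params.p_mild_moderate)
    return np.where(severe, 2, np.where(mild, 1, 0)).astype(np.int8)


def draw_adverse_event(
    params: InterventionParams, strategy: str, rng: np.random.Generator
) -> str:
    """Single first-month adverse-event draw; SOC always returns 'none'."""
    code = int(classify_adverse_event(params, strategy, rng.random()))
    return ("none", "mild_moderate", "severe")[code]


def ae_cost(params: InterventionParams, event_code: np.ndarray) -> np.ndarray:
    """One-time adverse-event cost (both perspectives) by event code."""
    return np.choose(
        event_code, [0.0, params.cost_ae_mild, params.cost_ae_severe]
    )


def ae_qaly_decrement(params: InterventionParams, event_code: np.ndarray) -> np.ndarray:
    """One-time QALY decrement (utility-days / 365.25) by event code."""
    return np.choose(
        event_code,
        [
            0.0,
            params.mild_decrement_days / DAYS_PER_YEAR,
            params.severe_decrement_days / DAYS_PER_YEAR,
        ],
    )


def expected_first_month_excess_cost(params: InterventionParams) -> float:
    """Expected month-0 CB cost in excess of SOC: infusion + expected AE cost."""
    return (
        params.cost_infusion
        + params.p_mild_moderate * params.cost_ae_mild
        + params.p_severe * params.cost_ae_severe
    )
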