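"""Utility mapping and QALY accrual.

Children (ages 2-17) get a utility from a published linear mapping of the
three adaptive-behavior subscales, symptom-severity score, and log IQ,
clamped to [-0.36, 1].  Adults (18+) get a single constant utility that is
identical across strategies; its source value is unprinted, so it is a free
parameter set by :func:`calibrate_adult_utility` against the reported
standard-of-care undiscounted lifetime QALYs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .config import ModelConfig
    from .life_tables import LifeTable

__all__ = [
    "QolParams",
    "CalibrationError",
    "child_utility",
    "monthly_qaly",
    "calibrate_adult_utility",
]


class CalibrationError(RuntimeError):
    """Raised when the calibration target is unreachable within bounds."""


@dataclass
class QolParams:
    beta0: float = -0.1630
    beta_comm: float = 0.0037
    beta_dls: float = 0.0046
    beta_soc: float = 0.0010
    beta_ados: float = -0.005
    beta_logiq: float = 0.024
    log_base: str = "natural"  # or "base10"
    utility_min: float = -0.36
    utility_max: float = 1.0
    #: adult constant utility; unprinted in the source, set by calibration.
    adult_utility: float = 0.66
    child_age_limit: float = 18.0

    def __post_init__(self) -> None:
        if self.utility_min >= self.utility_max:
            raise ValueError("utility_min must be below utility_max")
        if self.log_base not in ("natural", "base10"):
            raise ValueError("log_base must be 'natural' or 'base10'")
        if not self.utility_min <= self.adult_utility <= self.utility_max:
            raise ValueError("adult_utility outside utility bounds")


def child_utility(
    params: QolParams,
    comm: np.ndarray | float,
    dls: np.ndarray | float,
    soc: np.ndarray | float,
    ados: float,
    iq: float,
) -> np.ndarray | float:
    """Linear utility mapping for ages 2-17, clamped to the utility bounds."""
    if iq <= 0:
        raise ValueError("iq must be positive")
    log_iq = math.log(iq) if params.log_base == "natural" else math.log10(iq)
    raw = (
        params.beta0
        + params.beta_comm * np.asarray(comm, dtype=float)
        + params.beta_dls * np.asarray(dls, dtype=float)
        + params.beta_soc * np.asarray(soc, dtype=float)
        + params.beta_ados * ados
        + params.beta_logiq * log_iq
    )
    clamped = np.clip(raw, params.utility_min, params.utility_max)
    return float(clamped) if np.ndim(clamped) == 0 else clamped


def monthly_qaly(
    utility: float, discount_rate: float, months_since_entry: int
) -> tuple[float, float]:
    """(undiscounted, discounted) QALY increment for one lived month.

    Discounting uses the month-start exponent with entry (age 2) as time
    zero: discounted = (u/12) * (1+r)^(-m/12).
    """
    if months_since_entry < 0:
        raise ValueError("months_since_entry must be nonnegative")
    undisc = utility / 12.0
    disc = undisc * (1.0 + discount_rate) ** (-months_since_entry / 12.0)
    return undisc, disc


def calibrate_adult_utility(
    config: "ModelConfig",
    table: "LifeTable",
    target_undiscounted_soc_qalys: float = 40.75,
    tolerance: float = 1e-4,
    max_iter: int = 60,
) -> float:
    """Find the adult utility reproducing the target SOC undiscounted QALYs.

    Mean lifetime QALYs are exactly affine in the adult constant (adults
    accrue ``u * alive-months / 12``), so a monotone bisection on [0, 1]
    against paired endpoint simulations converges; the returned constant is
    verified with a final simulation run.
    """
    from .engine import run_cohort

    lo, hi = 0.0, 1.0

    def soc_qalys(u: float) -> float:
        cfg = config.with_overrides({"qol.adult_utility": u})
        return run_cohort(cfg, "soc", table=table).mean_qaly_undiscounted

    f_lo, f_hi = soc_qalys(lo), soc_qalys(hi)
    if not f_lo <= target_undiscounted_soc_qalys <= f_hi:
        raise CalibrationError(
            f"target {target_undiscounted_soc_qalys} outside reachable range "
            f"[{f_lo:.4f}, {f_hi:.4f}] for adult_utility in [0, 1]"
        )
    # Affine in u: bisect on the exact interpolant (cheap), then verify.
    slope = f_hi - f_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f_lo + slope * mid  # exact: QALYs are affine in adult_utility
        if abs(f_mid - target_undiscounted_soc_qalys) <= tolerance / 2:
            break
        if f_mid < target_undiscounted_soc_qalys:
            lo = mid
        else:
            hi = mid
    else:  # pragma: no cover - bisection to machine precision well before 60
        mid = 0.5 * (lo + hi)
    achieved = soc_qalys(mid)
    if abs(achieved - target_undiscounted_soc_qalys) > max(tolerance, 1e-6):
        raise CalibrationError(
            f"calibration verification failed: achieved {achieved:.6f} "
            f"vs target {target_undiscounted_soc_qalys}"
        )
    config.qol.adult_utility = mid
    return mid
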