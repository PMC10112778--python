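"""Monthly microsimulation engine with common random numbers.

Each simulated individual enters at age 2 and is followed monthly until
death or the age cap.  Random inputs are organized into purpose-specific
substreams keyed on (seed, stream id) so that the standard-of-care (SOC) and
cord-blood (CB) arms share every draw except those that only exist in the CB
arm (adverse events); with identical parameters the two arms are
bit-identical (common random numbers).

The cohort is simulated as a structure of arrays.  Subscale scores can only
change during months 0-59 (ages 2-7), so utilities are looped over those
months only; the frozen child period (ages 7-18) and adulthood accrue in
closed form via geometric discount sums, which is exactly equivalent to the
month-by-month loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from . import intervention as iv
from . import natural_history as nh
from .costs import adult_annual_costs
from .life_tables import LifeTable, monthly_death_probabilities
from .natural_history import STRATA
from .qol import child_utility

if TYPE_CHECKING:  # pragma: no cover
    from .config import ModelConfig

__all__ = [
    "EngineConfig",
    "StrategyResult",
    "CEResult",
    "CohortLedger",
    "simulate_individual",
    "run_cohort",
    "run_pair",
    "compare",
    "cost_effectiveness",
    "threshold_class",
]

log = logging.getLogger("asdcem")

# Substream ids: fixed constants so every purpose has a dedicated generator.
_S_BASELINE = 11
_S_GROWTH = 12
_S_GROWTH_MONTHLY = 13
_S_MORTALITY = 14
_S_TRIAL_COMM = 15
_S_TRIAL_SOC = 16
_S_TRIAL_DLS = 17
_S_AE = 18


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class EngineConfig:
    n_individuals: int = 100_000
    seed: int = 20230418
    discount_rate: float = 0.03
    perspective: str = "both"  # societal | payer | both
    trial_period_mode: str = "substitute"  # or "additive"
    #: disables trial-period changes; natural-history growth runs over all of
    #: ages 2-7 (used to reproduce the composite-trajectory validation).
    validation_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be nonnegative")
        if self.trial_period_mode not in ("substitute", "additive"):
            raise ValueError("trial_period_mode must be 'substitute' or 'additive'")
        if self.perspective not in ("societal", "payer", "both"):
            raise ValueError("perspective must be societal, payer, or both")


@dataclass
class CohortLedger:
    """Per-individual outcome arrays for one strategy run."""

    death_month: np.ndarray  # month index of death (cap forced)
    age_at_death: np.ndarray
    baseline_composite: np.ndarray
    comm_change_6m: np.ndarray  # realized communication change at month 6
    composite_change_2_7: np.ndarray  # composite at age 7 minus baseline
    stratum: np.ndarray  # codes: 0 gt85, 1 70to85, 2 lt70, -1 died young
    ae_event: np.ndarray  # 0 none, 1 mild/moderate, 2 severe
    qaly_undiscounted: np.ndarray
    qaly_discounted: np.ndarray
    cost_societal_undiscounted: np.ndarray
    cost_societal_discounted: np.ndarray
    cost_payer_undiscounted: np.ndarray
    cost_payer_discounted: np.ndarray
    payer_cost_5yr_undiscounted: np.ndarray
    final_comm: np.ndarray
    final_dls: np.ndarray
    final_soc: np.ndarray

    @property
    def n(self) -> int:
        return len(self.death_month)


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(x)), se


@dataclass
class StrategyResult:
    """Cohort-mean outcomes (and standard errors) for one strategy arm."""

    strategy: str
    n: int
    seed: int
    mean_qaly_undiscounted: float
    mean_qaly_discounted: float
    mean_cost_societal_undiscounted: float
    mean_cost_societal_discounted: float
    mean_cost_payer_undiscounted: float
    mean_cost_payer_discounted: float
    mean_age_at_death: float
    mean_composite_change_2_7: float
    mean_comm_change_6m: float
    stratum_shares: dict[str, float]
    se: dict[str, float]
    ledger: Optional[CohortLedger] = field(default=None, repr=False)

    def as_rows(self) -> list[dict]:
        """Long-format (strategy, metric, value, se) rows for CSV output."""
        rows = []
        for metric, value in [
            ("qaly_undiscounted", self.mean_qaly_undiscounted),
            ("qaly_discounted", self.mean_qaly_discounted),
            ("cost_societal_undiscounted", self.mean_cost_societal_undiscounted),
            ("cost_societal_discounted", self.mean_cost_societal_discounted),
            ("cost_payer_undiscounted", self.mean_cost_payer_undiscounted),
            ("cost_payer_discounted", self.mean_cost_payer_discounted),
            ("age_at_death", self.mean_age_at_death),
            ("composite_change_2_7", self.mean_composite_change_2_7),
            ("comm_change_6m", self.mean_comm_change_6m),
        ]:
            rows.append(
                {
                    "strategy": self.strategy,
                    "metric": metric,
                    "value": value,
                    "se": self.se.get(metric, float("nan")),
                }
            )
        for stratum, share in self.stratum_shares.items():
            rows.append(
                {
                    "strategy": self.strategy,
                    "metric": f"stratum_share_{stratum}",
                    "value": share,
                    "se": float("nan"),
                }
            )
        return rows


@dataclass
class CEResult:
    """Incremental cost-effectiveness of CB over SOC (discounted)."""

    perspective: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: Optional[str]  # 'dominant' | 'dominated' | None
    threshold_class: str
    delta_cost_se: float = 0.0
    delta_qaly_se: float = 0.0

    @property
    def label(self) -> str:
        return self.dominance if self.dominance else f"{self.icer:,.0f}/QALY"


def _discount_powers(discount_rate: float, n_months: int) -> np.ndarray:
    """delta^m for m = 0..n_months, delta = (1+r)^(-1/12)."""
    delta = (1.0 + discount_rate) ** (-1.0 / 12.0)
    return delta ** np.arange(n_months + 1)


def _gsum(dpow: np.ndarray, discount_rate: float, a: np.ndarray, b: np.ndarray):
    """sum_{m=a}^{b-1} delta^m, elementwise; b >= a required."""
    if discount_rate == 0.0:
        return (b - a).astype(float)
    delta = (1.0 + discount_rate) ** (-1.0 / 12.0)
    return (dpow[a] - dpow[b]) / (1.0 - delta)


def _death_months(
    config: "ModelConfig", table: LifeTable, u: np.ndarray
) -> tuple[np.ndarray, int]:
    """Inverse-CDF death month for each uniform draw; cap death forced.

    Equivalent in law to a month-by-month survival test against the same
    step-function monthly probabilities, and identical across strategies
    (mortality is strategy-independent).
    """
    entry = config.cohort.entry_age
    p = monthly_death_probabilities(table, config.mortality, entry_age=entry)
    n_months = len(p)
    cdf = 1.0 - np.cumprod(1.0 - np.concatenate([p, [1.0]]))
    cdf[-1] = 1.0
    d = np.searchsorted(cdf, u, side="right").astype(np.int64)
    return d, n_months


def _simulate(config: "ModelConfig", table: LifeTable, strategy: str, n: int) -> CohortLedger:
    eng = config.engine
    seed = eng.seed
    params_nh = config.natural_history
    params_iv = config.intervention
    params_q = config.qol
    params_c = config.costs
    cohort = config.cohort
    entry = cohort.entry_age

    # --- shared per-individual random inputs (common random numbers) ------
    baseline = nh.draw_baseline_scores(params_nh, _rng(seed, _S_BASELINE), n)
    bands = params_nh.monthly_change
    z_growth = _rng(seed, _S_GROWTH).standard_normal((n, len(bands)))
    band_rates = np.stack(
        [b.mean + b.sd * z_growth[:, i] for i, b in enumerate(bands)], axis=1
    )
    growth_monthly_rng = _rng(seed, _S_GROWTH_MONTHLY)
    u_mort = _rng(seed, _S_MORTALITY).random(n)
    z_comm = _rng(seed, _S_TRIAL_COMM).standard_normal(n)
    z_soc = _rng(seed, _S_TRIAL_SOC).standard_normal(n)
    z_dls = _rng(seed, _S_TRIAL_DLS).standard_normal(n)
    u_ae = _rng(seed, _S_AE).random(n)

    death_month, n_months = _death_months(config, table, u_mort)
    month_18 = int(round((params_q.child_age_limit - entry) * 12))  # 192
    month_7 = int(round((params_nh.growth_stop_age - entry) * 12))  # 60
    trial_months = params_iv.effect_window_months

    # --- strategy-specific first-month draws ------------------------------
    ae = iv.classify_adverse_event(params_iv, strategy, u_ae)
    severe = ae == 2
    d_comm = iv.realized_comm_change(params_iv, strategy, severe, z_comm)
    if eng.validation_mode:
        d_comm = np.zeros(n)
        d_soc = np.zeros(n)
        d_dls = np.zeros(n)
    else:
        d_soc = params_iv.soc_change_both.mean + params_iv.soc_change_both.sd * z_soc
        d_dls = params_iv.dls_change_both.mean + params_iv.dls_change_both.sd * z_dls

    # --- subscale evolution and child utility, months 0..month_7-1 --------
    comm = baseline.copy()
    dls = baseline.copy()
    soc = baseline.copy()
    floor, ceil = params_nh.vabs_floor, params_nh.vabs_ceiling
    dpow = _discount_powers(eng.discount_rate, n_months + 1)
    qaly_u = np.zeros(n)
    qaly_d = np.zeros(n)
    comm_change_6m = np.zeros(n)

    for m in range(month_7):
        age = entry + m / 12.0
        in_trial = (not eng.validation_mode) and m < trial_months
        if in_trial:
            comm += d_comm / trial_months
            soc += d_soc / trial_months
            dls += d_dls / trial_months
        growth_active = eng.validation_mode or eng.trial_period_mode == "additive" or not in_trial
        if growth_active:
            band_idx = next(
                i for i, b in enumerate(bands) if b.age_lo <= age < b.age_hi
            )
            if params_nh.per_individual_rates:
                inc = band_rates[:, band_idx]
            else:
                b = bands[band_idx]
                inc = b.mean + b.sd * growth_monthly_rng.standard_normal(n)
            comm = comm + inc
            dls = dls + inc
            soc = soc + inc
        np.clip(comm, floor, ceil, out=comm)
        np.clip(dls, floor, ceil, out=dls)
        np.clip(soc, floor, ceil, out=soc)
        if m == trial_months - 1:
            comm_change_6m = comm - baseline
        alive = death_month > m
        u = child_utility(params_q, comm, dls, soc, cohort.ados_css, cohort.nviq)
        qaly_u += np.where(alive, u, 0.0) / 12.0
        qaly_d += np.where(alive, u, 0.0) / 12.0 * dpow[m]

    composite = (comm + dls + soc) / 3.0
    composite_change_2_7 = composite - baseline
    u7 = np.asarray(
        child_utility(params_q, comm, dls, soc, cohort.ados_css, cohort.nviq)
    )

    # --- frozen child period, months month_7..month_18-1 (closed form) ----
    child_end = np.minimum(death_month, month_18)
    start_b = np.minimum(np.maximum(child_end, month_7), month_18)
    months_b = start_b - month_7
    qaly_u += u7 * months_b / 12.0
    qaly_d += u7 / 12.0 * _gsum(dpow, eng.discount_rate, np.full(n, month_7), start_b)

    # --- adult stratum and adult period, months month_18..death -----------
    stratum_code = np.where(
        composite > 85.0, 0, np.where(composite >= 70.0, 1, 2)
    ).astype(np.int8)
    stratum_code = np.where(death_month > month_18, stratum_code, -1)
    adult_start = np.maximum(death_month, month_18)
    months_adult = death_month - np.minimum(death_month, month_18)
    g_adult = _gsum(dpow, eng.discount_rate, np.full(n, month_18), adult_start)
    qaly_u += params_q.adult_utility * months_adult / 12.0
    qaly_d += params_q.adult_utility / 12.0 * g_adult

    # --- costs -------------------------------------------------------------
    g_child = _gsum(dpow, eng.discount_rate, np.zeros(n, dtype=int), child_end)
    cost_soc_u = params_c.child_societal_annual / 12.0 * child_end
    cost_soc_d = params_c.child_societal_annual / 12.0 * g_child
    cost_pay_u = params_c.child_payer_annual / 12.0 * child_end
    cost_pay_d = params_c.child_payer_annual / 12.0 * g_child

    adult_societal = np.zeros(3)
    for code, stratum in enumerate(STRATA):
        adult_societal[code] = sum(adult_annual_costs(params_c, stratum).values())
    adult_payer = params_c.adult_medical / params_c.adult_cost_divisor
    societal_rate = np.where(stratum_code >= 0, adult_societal[stratum_code], 0.0)
    cost_soc_u += societal_rate / 12.0 * months_adult
    cost_soc_d += societal_rate / 12.0 * g_adult
    cost_pay_u += adult_payer / 12.0 * months_adult
    cost_pay_d += adult_payer / 12.0 * g_adult

    payer_5yr = params_c.child_payer_annual / 12.0 * np.minimum(death_month, 60)

    # --- month-0 intervention extras (CB only; time 0, no discounting) ----
    alive0 = death_month > 0
    if strategy == iv.CB and not eng.validation_mode:
        extra = (params_iv.cost_infusion + iv.ae_cost(params_iv, ae)) * alive0
        cost_soc_u += extra
        cost_soc_d += extra
        cost_pay_u += extra
        cost_pay_d += extra
        payer_5yr += extra
        dec = iv.ae_qaly_decrement(params_iv, ae) * alive0
        qaly_u -= dec
        qaly_d -= dec

    return CohortLedger(
        death_month=death_month,
        age_at_death=entry + death_month / 12.0,
        baseline_composite=baseline,
        comm_change_6m=comm_change_6m,
        composite_change_2_7=composite_change_2_7,
        stratum=stratum_code,
        ae_event=ae,
        qaly_undiscounted=qaly_u,
        qaly_discounted=qaly_d,
        cost_societal_undiscounted=cost_soc_u,
        cost_societal_discounted=cost_soc_d,
        cost_payer_undiscounted=cost_pay_u,
        cost_payer_discounted=cost_pay_d,
        payer_cost_5yr_undiscounted=payer_5yr,
        final_comm=comm,
        final_dls=dls,
        final_soc=soc,
    )


def _resolve_table(config: "ModelConfig", table: Optional[LifeTable]) -> LifeTable:
    if table is not None:
        return table
    if config.lifetable_path is None:
        raise ValueError("no lifetable: pass table= or set lifetable_path in config")
    from .life_tables import load_lifetable

    return load_lifetable(config.lifetable_path)


def simulate_individual(
    config: "ModelConfig",
    id: int,
    strategy: str,
    table: Optional[LifeTable] = None,
) -> nh.IndividualState:
    """Run one individual's ledger under its (seed, id) substream position.

    Individual ``id`` occupies position ``id`` in every purpose-specific
    substream, so the same id is paired across strategies; the returned
    state matches row ``id`` of a cohort run with n > id.
    """
    table = _resolve_table(config, table)
    ledger = _simulate(config, table, strategy, id + 1)
    i = id
    stratum = STRATA[ledger.stratum[i]] if ledger.stratum[i] >= 0 else "unassigned"
    return nh.IndividualState(
        id=id,
        age=float(ledger.age_at_death[i]),
        alive=False,
        vabs_comm=float(ledger.final_comm[i]),
        vabs_dls=float(ledger.final_dls[i]),
        vabs_soc=float(ledger.final_soc[i]),
        adult_stratum=stratum,
        qaly_undiscounted=float(ledger.qaly_undiscounted[i]),
        qaly_discounted=float(ledger.qaly_discounted[i]),
        cost_societal_undiscounted=float(ledger.cost_societal_undiscounted[i]),
        cost_societal_discounted=float(ledger.cost_societal_discounted[i]),
        cost_payer_undiscounted=float(ledger.cost_payer_undiscounted[i]),
        cost_payer_discounted=float(ledger.cost_payer_discounted[i]),
    )


def run_cohort(
    config: "ModelConfig",
    strategy: str,
    table: Optional[LifeTable] = None,
    n: Optional[int] = None,
    keep_ledger: bool = True,
) -> StrategyResult:
    """Simulate a cohort for one strategy and aggregate mean outcomes."""
    table = _resolve_table(config, table)
    n = n if n is not None else config.engine.n_individuals
    log.info(
        "run_cohort strategy=%s n=%d seed=%d mode=%s validation=%s",
        strategy, n, config.engine.seed,
        config.engine.trial_period_mode, config.engine.validation_mode,
    )
    ledger = _simulate(config, table, strategy, n)

    se: dict[str, float] = {}
    means: dict[str, float] = {}
    for metric, arr in [
        ("qaly_undiscounted", ledger.qaly_undiscounted),
        ("qaly_discounted", ledger.qaly_discounted),
        ("cost_societal_undiscounted", ledger.cost_societal_undiscounted),
        ("cost_societal_discounted", ledger.cost_societal_discounted),
        ("cost_payer_undiscounted", ledger.cost_payer_undiscounted),
        ("cost_payer_discounted", ledger.cost_payer_discounted),
        ("age_at_death", ledger.age_at_death),
    ]:
        means[metric], se[metric] = _mean_se(arr)

    month_7 = int(round((config.natural_history.growth_stop_age - config.cohort.entry_age) * 12))
    alive7 = ledger.death_month > month_7
    comp_change, se["composite_change_2_7"] = (
        _mean_se(ledger.composite_change_2_7[alive7]) if alive7.any() else (float("nan"), 0.0)
    )
    alive6 = ledger.death_month > config.intervention.effect_window_months
    comm6, se["comm_change_6m"] = (
        _mean_se(ledger.comm_change_6m[alive6]) if alive6.any() else (float("nan"), 0.0)
    )
    adults = ledger.stratum >= 0
    n_adults = int(adults.sum())
    shares = {
        stratum: float((ledger.stratum == code).sum()) / n_adults if n_adults else float("nan")
        for code, stratum in enumerate(STRATA)
    }

    return StrategyResult(
        strategy=strategy,
        n=n,
        seed=config.engine.seed,
        mean_qaly_undiscounted=means["qaly_undiscounted"],
        mean_qaly_discounted=means["qaly_discounted"],
        mean_cost_societal_undiscounted=means["cost_societal_undiscounted"],
        mean_cost_societal_discounted=means["cost_societal_discounted"],
        mean_cost_payer_undiscounted=means["cost_payer_undiscounted"],
        mean_cost_payer_discounted=means["cost_payer_discounted"],
        mean_age_at_death=means["age_at_death"],
        mean_composite_change_2_7=comp_change,
        mean_comm_change_6m=comm6,
        stratum_shares=shares,
        se=se,
        ledger=ledger if keep_ledger else None,
    )


def run_pair(
    config: "ModelConfig",
    table: Optional[LifeTable] = None,
    n: Optional[int] = None,
) -> tuple[StrategyResult, StrategyResult]:
    """Run SOC and CB under the same seed (common random numbers)."""
    table = _resolve_table(config, table)
    return (
        run_cohort(config, iv.SOC, table=table, n=n),
        run_cohort(config, iv.CB, table=table, n=n),
    )


def threshold_class(icer: Optional[float], dominance: Optional[str] = None) -> str:
    """Willingness-to-pay band: <50k, 50k-100k, 100k-150k, >150k USD/QALY."""
    if dominance == "dominant":
        return "<50k"
    if dominance == "dominated" or icer is None:
        return ">150k"
    if icer < 50_000:
        return "<50k"
    if icer < 100_000:
        return "50k-100k"
    if icer < 150_000:
        return "100k-150k"
    return ">150k"


def cost_effectiveness(
    delta_cost: float, delta_qaly: float
) -> tuple[Optional[float], Optional[str]]:
    """(icer, dominance label) from discounted incremental cost and QALYs."""
    if delta_qaly > 0 and delta_cost > 0:
        return delta_cost / delta_qaly, None
    if delta_qaly <= 0 and delta_cost > 0:
        return None, "dominated"
    if delta_qaly >= 0 and delta_cost <= 0:
        return None, "dominant"
    # cheaper and less effective: report the south-west ratio without a label
    return delta_cost / delta_qaly, None


def compare(
    soc: StrategyResult, cb: StrategyResult, perspective: str = "societal"
) -> CEResult:
    """Paired incremental cost-effectiveness of CB over SOC (discounted)."""
    if soc.strategy != iv.SOC or cb.strategy != iv.CB:
        raise ValueError("compare(soc, cb) expects the SOC then the CB result")
    if soc.n != cb.n or soc.seed != cb.seed:
        raise ValueError("arms were not run under the same seed/config")
    if soc.ledger is not None and cb.ledger is not None:
        dq_arr = cb.ledger.qaly_discounted - soc.ledger.qaly_discounted
        if perspective == "payer":
            dc_arr = cb.ledger.cost_payer_discounted - soc.ledger.cost_payer_discounted
        else:
            dc_arr = (
                cb.ledger.cost_societal_discounted - soc.ledger.cost_societal_discounted
            )
        delta_qaly, dq_se = _mean_se(dq_arr)
        delta_cost, dc_se = _mean_se(dc_arr)
    else:
        delta_qaly = cb.mean_qaly_discounted - soc.mean_qaly_discounted
        if perspective == "payer":
            delta_cost = cb.mean_cost_payer_discounted - soc.mean_cost_payer_discounted
        else:
            delta_cost = (
                cb.mean_cost_societal_discounted - soc.mean_cost_societal_discounted
            )
        dq_se = dc_se = float("nan")
    icer, dominance = cost_effectiveness(delta_cost, delta_qaly)
    return CEResult(
        perspective=perspective,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        dominance=dominance,
        threshold_class=threshold_class(icer, dominance),
        delta_cost_se=dc_se,
        delta_qaly_se=dq_se,
    )
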