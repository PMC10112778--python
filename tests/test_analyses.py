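import numpy as np
import pytest

from asdcem import engine as eng
from asdcem.analyses import (
    BIAParams,
    SCENARIOS,
    SensitivitySpec,
    budget_impact,
    default_tornado_specs,
    scenario,
    tornado,
    two_way_grid,
)


class TestSensitivitySpec:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            SensitivitySpec("intervention.cost_infusion", 20_000, 10_000, 15_000)

    def test_defaults_include_published_beta_extremes(self):
        specs = {s.parameter: s for s in default_tornado_specs()}
        beta = specs["qol.beta_comm"]
        assert (beta.low, beta.high) == (0.0019, 0.0074)


class TestTornado:
    def test_zero_width_bar(self, config_small, table):
        spec = SensitivitySpec("intervention.cost_infusion", 15_000, 15_000, 15_000)
        df = tornado(config_small, [spec], table=table)
        assert df.loc[0, "span"] == 0.0

    def test_infusion_span_matches_linearity_oracle(self, config_small, table):
        spec = SensitivitySpec("intervention.cost_infusion", 8_000, 45_000, 15_000)
        df = tornado(config_small, [spec], table=table)
        soc, cb = eng.run_pair(config_small, table=table)
        dq = eng.compare(soc, cb).delta_qaly
        assert df.loc[0, "span"] == pytest.approx(37_000 / dq, rel=1e-6)

    def test_beta_comm_scales_delta_qaly_proportionally(self, config_small, table):
        """Discounted incremental QALYs are proportional to the communication
        coefficient (AE decrements excluded so the proportionality is exact)."""
        base = config_small.with_overrides(
            {
                "intervention.p_mild_moderate": 0.0,
                "intervention.p_severe": 0.0,
                # widen utility bounds so the ceiling clamp cannot bend the
                # exact linearity in beta_comm
                "qol.utility_max": 10.0,
                "qol.utility_min": -10.0,
            }
        )
        dqs = {}
        for beta in (0.0019, 0.0037, 0.0074):
            cfg = base.with_overrides({"qol.beta_comm": beta})
            soc, cb = eng.run_pair(cfg, table=table)
            dqs[beta] = eng.compare(soc, cb).delta_qaly
        assert dqs[0.0074] / dqs[0.0037] == pytest.approx(2.0, rel=1e-6)
        assert dqs[0.0019] / dqs[0.0037] == pytest.approx(0.0019 / 0.0037, rel=1e-6)

    def test_sorted_by_span_and_deterministic(self, config_small, table):
        specs = [
            SensitivitySpec("intervention.cost_infusion", 8_000, 45_000, 15_000),
            SensitivitySpec("intervention.cost_ae_mild", 0.0, 4_200, 2_100.0),
        ]
        df1 = tornado(config_small, specs, table=table)
        df2 = tornado(config_small, specs, table=table)
        assert (df1["span"].values == sorted(df1["span"].values, reverse=True)).all()
        assert df1.equals(df2)

    def test_unknown_key_rejected(self, config_small, table):
        from asdcem.config import ConfigError

        spec = SensitivitySpec("intervention.cost_of_nothing", 0, 1, 0.5)
        with pytest.raises(ConfigError):
            tornado(config_small, [spec], table=table)


def icer_order_value(df):
    """ICER with dominance mapped to the ends of the ordering scale."""
    icer = df["icer"].to_numpy(copy=True)
    icer[(df["dominance"] == "dominant").to_numpy()] = -np.inf
    icer[(df["dominance"] == "dominated").to_numpy()] = np.inf
    return icer


class TestTwoWayGrid:
    def test_monotone_in_efficacy_and_cost(self, config_small, table):
        df = two_way_grid(
            config_small, [1.0, 3.0, 6.0], [3_000.0, 15_000.0, 33_000.0], table=table
        )
        df["order_icer"] = icer_order_value(df)
        for cost, col in df.groupby("cost"):
            icers = col.sort_values("efficacy")["order_icer"].values
            assert (np.diff(icers) <= 0).all()  # nonincreasing in efficacy
        for efficacy, row in df.groupby("efficacy"):
            icers = row.sort_values("cost")["order_icer"].values
            assert (np.diff(icers) >= 0).all()  # nondecreasing in cost

    def test_basecase_cell_has_class_column(self, config_small, table):
        df = two_way_grid(config_small, [3.0], [15_000.0], table=table)
        assert df.loc[0, "threshold_class"] in {"<50k", "50k-100k", "100k-150k", ">150k"}

    def test_empty_grid_rejected(self, config_small, table):
        with pytest.raises(ValueError):
            two_way_grid(config_small, [], [15_000.0], table=table)


class TestScenarios:
    def test_zero_efficacy_dominated(self, config_small, table):
        ce = scenario(config_small, "zero_efficacy", table=table)
        assert ce.dominance == "dominated"
        assert ce.icer is None

    def test_worst_case_worse_than_best_case(self, config_small, table):
        best = scenario(config_small, "best_case", table=table)
        worst = scenario(config_small, "worst_case", table=table)
        best_order = -np.inf if best.dominance == "dominant" else best.icer
        assert worst.dominance is None  # expensive and barely effective
        assert worst.icer > best_order
        assert worst.icer > 1_000_000  # worst case is far beyond any threshold

    def test_payer_scenario_matches_excess_cost_oracle(self, config_small, table):
        """Payer incremental cost is the infusion plus realized AE costs."""
        ce = scenario(config_small, "payer", table=table)
        soc, cb = eng.run_pair(config_small, table=table)
        ae = cb.ledger.ae_event
        realized = (
            15_000.0
            + ((ae == 1).mean() * 2_100.0 + (ae == 2).mean() * 11_571.0)
        )
        assert ce.perspective == "payer"
        assert ce.delta_cost == pytest.approx(realized, rel=1e-6)

    def test_reduced_adult_costs_lowers_both_arms_not_icer(self, config_small, table):
        base_soc, base_cb = eng.run_pair(config_small, table=table)
        cfg = config_small.with_overrides(SCENARIOS["reduced_adult_costs"])
        red_soc, red_cb = eng.run_pair(cfg, table=table)
        assert red_soc.mean_cost_societal_discounted < base_soc.mean_cost_societal_discounted
        assert red_cb.mean_cost_societal_discounted < base_cb.mean_cost_societal_discounted

    def test_mcid_only_truncates_small_draws(self, config_small, table):
        cfg = config_small.with_overrides(SCENARIOS["mcid_only"])
        cb = eng.run_cohort(cfg, "cb", table=table)
        severe = cb.ledger.ae_event == 2
        draws = cb.ledger.comm_change_6m[~severe]
        # every non-severe realized change is either >= 2.0 or ~0 (growth only)
        assert ((draws >= 2.0) | (np.abs(draws) < 1e-9)).all()

    def test_mcid_mean_matches_truncated_normal_oracle(self, config_small, table):
        from scipy import stats

        cfg = config_small.with_overrides(SCENARIOS["mcid_only"])
        cfg.engine.n_individuals = 50_000
        cfg = cfg.with_overrides(
            {"intervention.p_mild_moderate": 0.0, "intervention.p_severe": 0.0}
        )
        cb = eng.run_cohort(cfg, "cb", table=table)
        # E[X 1(X >= 2)] for X ~ N(3, 7.9)
        mu, sd, t = 3.0, 7.9, 2.0
        z = (t - mu) / sd
        oracle = mu * stats.norm.sf(z) + sd * stats.norm.pdf(z)
        se = sd / np.sqrt(cfg.engine.n_individuals)
        assert abs(cb.mean_comm_change_6m - oracle) < 4 * se

    def test_unknown_scenario_rejected(self, config_small, table):
        with pytest.raises(KeyError):
            scenario(config_small, "miracle_case", table=table)


class TestBudgetImpact:
    def test_zero_uptake_is_free(self, config_small, table):
        result = budget_impact(config_small, BIAParams(uptake=0.0), table=table)
        assert result["total"] == 0.0

    def test_per_person_increment_near_arithmetic_oracle(self, config_small, table):
        result = budget_impact(config_small, table=table)
        # oracle: infusion + expected AE costs; MC error from AE draws only
        oracle = 15_000 + 0.092 * 2_100 + 0.034 * 11_571
        ae_sd = np.sqrt(
            0.092 * 2_100**2 + 0.034 * 11_571**2 - (0.092 * 2_100 + 0.034 * 11_571) ** 2
        )
        se = ae_sd / np.sqrt(config_small.engine.n_individuals)
        assert abs(result["per_person_increment"] - oracle) < 4 * se

    def test_linear_in_uptake_and_population(self, config_small, table):
        full = budget_impact(config_small, BIAParams(uptake=1.0), table=table)
        fifth = budget_impact(config_small, BIAParams(uptake=0.2), table=table)
        half_pop = budget_impact(
            config_small, BIAParams(eligible_population=123_500), table=table
        )
        assert fifth["total"] == pytest.approx(0.2 * full["total"], rel=1e-12)
        assert half_pop["total"] == pytest.approx(0.5 * full["total"], rel=1e-12)

    def test_uptake_bounds_validated(self):
        with pytest.raises(ValueError):
            BIAParams(uptake=1.5)
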