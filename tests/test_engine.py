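import math

import numpy as np
import pytest

from asdcem import engine as eng
from asdcem.engine import CEResult, cost_effectiveness, threshold_class
from asdcem.life_tables import life_expectancy_from_age2
from asdcem.qol import QolParams, child_utility

from conftest import deterministic_overrides


class TestCostEffectiveness:
    def test_icer_division(self):
        icer, label = cost_effectiveness(14_000.0, 0.133)
        assert label is None
        assert icer == pytest.approx(105_263.16, abs=0.01)

    def test_dominated_when_no_qaly_gain(self):
        icer, label = cost_effectiveness(14_000.0, 0.0)
        assert icer is None and label == "dominated"
        icer, label = cost_effectiveness(14_000.0, -0.01)
        assert icer is None and label == "dominated"

    def test_dominant_when_costless_gain(self):
        icer, label = cost_effectiveness(0.0, 0.1)
        assert icer is None and label == "dominant"
        icer, label = cost_effectiveness(-5.0, 0.1)
        assert icer is None and label == "dominant"

    @pytest.mark.parametrize(
        "icer,expected",
        [
            (10_000, "<50k"),
            (75_000, "50k-100k"),
            (105_000, "100k-150k"),
            (200_000, ">150k"),
        ],
    )
    def test_threshold_bands(self, icer, expected):
        assert threshold_class(icer) == expected


class TestSingleIndividual:
    def test_n1_cohort_matches_simulate_individual(self, config_small, table):
        cfg = config_small
        state = eng.simulate_individual(cfg, 0, "cb", table=table)
        res = eng.run_cohort(cfg, "cb", table=table, n=1)
        assert state.qaly_undiscounted == res.ledger.qaly_undiscounted[0]
        assert state.qaly_discounted == res.ledger.qaly_discounted[0]
        assert state.cost_societal_discounted == res.ledger.cost_societal_discounted[0]
        assert state.age == res.ledger.age_at_death[0]

    def test_individual_position_in_larger_cohort(self, config_small, table):
        state = eng.simulate_individual(config_small, 5, "soc", table=table)
        res = eng.run_cohort(config_small, "soc", table=table, n=10)
        assert state.qaly_discounted == res.ledger.qaly_discounted[5]
        assert state.age == res.ledger.age_at_death[5]


class TestConservation:
    def test_unit_utility_no_discounting_gives_life_years(
        self, config_small, zero_mortality_table
    ):
        """With utility forced to 1 and r = 0, QALYs equal life-years from age 2."""
        cfg = config_small.with_overrides(
            {
                "qol.beta0": 1.0,
                "qol.beta_comm": 0.0,
                "qol.beta_dls": 0.0,
                "qol.beta_soc": 0.0,
                "qol.beta_ados": 0.0,
                "qol.beta_logiq": 0.0,
                "qol.adult_utility": 1.0,
                "engine.discount_rate": 0.0,
                "intervention.p_mild_moderate": 0.0,
                "intervention.p_severe": 0.0,
            }
        )
        res = eng.run_cohort(cfg, "soc", table=zero_mortality_table, n=100)
        np.testing.assert_allclose(res.ledger.qaly_undiscounted, 98.0, rtol=1e-9)
        np.testing.assert_allclose(res.ledger.qaly_discounted, 98.0, rtol=1e-9)

    def test_deterministic_rollout_matches_scalar_oracle(
        self, config_small, zero_mortality_table
    ):
        """Zero mortality, zero sds, SOC, r = 0: an independent scalar monthly
        rollout of the published recipe reproduces the engine's QALYs."""
        cfg = config_small.with_overrides(deterministic_overrides())
        cfg = cfg.with_overrides({"engine.discount_rate": 0.0})
        res = eng.run_cohort(cfg, "soc", table=zero_mortality_table, n=3)

        qparams = QolParams()
        comm = dls = socl = 71.8
        qaly = 0.0
        bands = {2: 0.05, 3: 0.05, 4: 0.14, 5: 0.14, 6: 0.14}
        for m in range(98 * 12):
            age = 2 + m / 12.0
            if m < 6:  # trial window substitutes for natural-history growth
                comm += 0.1 / 6
                socl += 3.2 / 6
                dls += 2.8 / 6
            elif age < 7:
                inc = bands[int(age)]
                comm += inc
                socl += inc
                dls += inc
            if age < 18:
                u = child_utility(qparams, comm, dls, socl, 16.7, 88.1)
            else:
                u = qparams.adult_utility
            qaly += u / 12.0
        np.testing.assert_allclose(res.ledger.qaly_undiscounted, qaly, rtol=1e-10)


class TestMortality:
    def test_mean_age_at_death_invariant_to_strategy(self, config_small, table):
        soc, cb = eng.run_pair(config_small, table=table)
        assert soc.mean_age_at_death == cb.mean_age_at_death
        np.testing.assert_array_equal(soc.ledger.death_month, cb.ledger.death_month)

    def test_monte_carlo_age_at_death_matches_analytic_oracle(self, config_large, table):
        res = eng.run_cohort(config_large, "soc", table=table, keep_ledger=True)
        oracle = life_expectancy_from_age2(table, config_large.mortality)
        se = res.se["age_at_death"]
        assert abs(res.mean_age_at_death - oracle) < 3 * se


class TestIcerStructure:
    def test_icer_linear_in_infusion_cost(self, config_small, table):
        """Infusion is paid at time zero, so ICER(c2) - ICER(c1) = (c2-c1)/dQ."""
        icers, dqs = {}, {}
        for cost in (8_000, 15_000, 25_000, 35_000, 45_000):
            cfg = config_small.with_overrides({"intervention.cost_infusion": float(cost)})
            soc, cb = eng.run_pair(cfg, table=table)
            ce = eng.compare(soc, cb)
            icers[cost] = ce.icer
            dqs[cost] = ce.delta_qaly
        dq = dqs[8_000]
        assert all(v == pytest.approx(dq, rel=1e-12) for v in dqs.values())
        costs = sorted(icers)
        assert all(icers[a] < icers[b] for a, b in zip(costs, costs[1:]))
        for cost in costs[1:]:
            assert icers[cost] - icers[8_000] == pytest.approx(
                (cost - 8_000) / dq, rel=1e-6
            )

    def test_paired_variance_smaller_than_independent(self, config_small, table):
        soc, cb = eng.run_pair(config_small, table=table)
        paired_var = np.var(cb.ledger.qaly_discounted - soc.ledger.qaly_discounted)
        independent_var = np.var(cb.ledger.qaly_discounted) + np.var(
            soc.ledger.qaly_discounted
        )
        assert paired_var < independent_var / 10

    def test_compare_rejects_mismatched_runs(self, config_small, table):
        soc, cb = eng.run_pair(config_small, table=table)
        other = config_small.with_overrides({"engine.seed": 1})
        cb_other = eng.run_cohort(other, "cb", table=table)
        with pytest.raises(ValueError):
            eng.compare(soc, cb_other)
        with pytest.raises(ValueError):
            eng.compare(cb, soc)  # wrong order


class TestStrategyResult:
    def test_rows_format(self, config_small, table):
        res = eng.run_cohort(config_small, "soc", table=table)
        rows = res.as_rows()
        metrics = {r["metric"] for r in rows}
        assert "qaly_discounted" in metrics
        assert "stratum_share_gt85" in metrics

    def test_reproducible_given_seed(self, config_small, table):
        a = eng.run_cohort(config_small, "cb", table=table)
        b = eng.run_cohort(config_small, "cb", table=table)
        np.testing.assert_array_equal(a.ledger.qaly_discounted, b.ledger.qaly_discounted)
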