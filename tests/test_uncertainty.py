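import dataclasses

import numpy as np
import pytest

from preventure.finance import project
from preventure.parameters import ParameterSpec, median_scenario
from preventure.uncertainty import (
    MonteCarloResult,
    ViabilityCriteria,
    breakeven_distribution,
    run_monte_carlo,
    summarize,
    viability_verdict,
)


def degenerate_set(table2):
    specs = {
        name: ParameterSpec(name, s.median, s.median, s.median, s.unit, s.kind)
        for name, s in table2.specs.items()
    }
    return dataclasses.replace(table2, specs=specs).with_run(n_iterations=50)


def shifted_triple(pset, name, delta):
    s = pset[name]
    return pset.with_spec(
        ParameterSpec(name, s.median + delta, s.min + delta, s.max + delta, s.unit, s.kind)
    )


class TestReproducibility:
    def test_same_seed_bitwise_identical(self, table2):
        small = table2.with_run(n_iterations=400)
        a, b = run_monte_carlo(small), run_monte_carlo(small)
        assert np.array_equal(a.npv, b.npv)
        assert np.array_equal(a.breakeven_year, b.breakeven_year)
        assert np.array_equal(a.irr, b.irr, equal_nan=True)

    def test_different_seed_differs(self, table2):
        a = run_monte_carlo(table2.with_run(n_iterations=400, seed=1))
        b = run_monte_carlo(table2.with_run(n_iterations=400, seed=2))
        assert not np.array_equal(a.npv, b.npv)


class TestDegenerateSet:
    def test_all_iterations_equal_deterministic_projection(self, table2):
        pset = degenerate_set(table2)
        mc = run_monte_carlo(pset)
        base = project(median_scenario(pset))
        assert np.allclose(mc.active_users, base.trajectory.active[:, None])
        assert np.allclose(mc.cumulative_final, base.cumulative_cash_flow[-1])
        assert np.unique(mc.breakeven_year).size == 1


class TestBreakevenDistribution:
    def test_probabilities_sum_to_one_exactly(self, mc_result):
        dist = breakeven_distribution(mc_result)
        assert dist.p_any + dist.p_never == pytest.approx(1.0, abs=0)
        assert np.all(dist.p_year >= 0) and 0 <= dist.p_never <= 1

    def test_always_breakeven_scenario(self, table2):
        # free product with zero costs: year-1 cumulative flow is positive
        specs = {}
        for name, s in table2.specs.items():
            if s.kind == "currency" and name != "price_monthly":
                specs[name] = ParameterSpec(name, 0, 0, 0, s.unit, s.kind)
            else:
                specs[name] = s
        pset = dataclasses.replace(table2, specs=specs).with_run(n_iterations=100)
        dist = breakeven_distribution(run_monte_carlo(pset))
        assert dist.p_year[0] == 1.0 and dist.p_never == 0.0

    def test_first_year_semantics(self, mc_result):
        """breakeven_year marks the first year the cumulative position
        clears zero; earlier years must be strictly negative."""
        idx = np.flatnonzero(mc_result.breakeven_year == 4)[:50]
        cum = np.cumsum(mc_result.net_cash_flow[:, idx], axis=0)
        assert np.all(cum[:3] < 0) and np.all(cum[3] >= 0)


class TestSummarize:
    def test_constant_metric_has_flat_percentiles(self, table2):
        mc = run_monte_carlo(degenerate_set(table2))
        table = summarize(mc, percentiles=(0.1, 0.5, 0.9))
        row = table.loc["npv"]
        assert row["p10"] == row["p50"] == row["p90"]

    def test_median_by_linear_interpolation(self):
        mc = MonteCarloResult(
            n=5,
            horizon=2,
            breakeven_year=np.zeros(5, dtype=int),
            cumulative_final=np.array([1.0, 2, 3, 4, 5]),
            npv=np.array([1.0, 2, 3, 4, 5]),
            irr=np.array([0.1, 0.2, np.nan, 0.4, 0.5]),
            active_users=np.ones((2, 5)),
            net_cash_flow=np.ones((2, 5)),
            revenue=np.ones((2, 5)),
            terminal=np.zeros(5),
        )
        table = summarize(mc, percentiles=(0.5,))
        assert table.loc["npv", "p50"] == 3
        assert table.loc["irr", "n_undefined"] == 1

    def test_invalid_percentiles_rejected(self, mc_result):
        with pytest.raises(ValueError):
            summarize(mc_result, percentiles=(1.5,))
        with pytest.raises(ValueError):
            summarize(mc_result, percentiles=())


class TestMonotoneCoupling:
    """With common random numbers, shifting a whole (min, median, max) triple
    moves the breakeven probability in the economically expected direction."""

    def test_price_up_weakly_increases_p_any(self, table2):
        small = table2.with_run(n_iterations=1500)
        base = breakeven_distribution(run_monte_carlo(small)).p_any
        up = breakeven_distribution(run_monte_carlo(shifted_triple(small, "price_monthly", 5.0))).p_any
        assert up >= base

    def test_cac_up_weakly_decreases_p_any(self, table2):
        small = table2.with_run(n_iterations=1500)
        base = breakeven_distribution(run_monte_carlo(small)).p_any
        up = breakeven_distribution(run_monte_carlo(shifted_triple(small, "cac", 50.0))).p_any
        assert up <= base


class TestViabilityVerdict:
    def test_free_running_venture_passes_everything(self, table2):
        """Only the launch outlay survives on the cost side: breakeven is
        immediate-ish, NPV is positive and the IRR on the small initial
        capital is enormous — every criterion passes."""
        specs = {}
        for name, s in table2.specs.items():
            if s.kind == "currency" and name not in ("price_monthly", "app_development"):
                specs[name] = ParameterSpec(name, 0, 0, 0, s.unit, s.kind)
            else:
                specs[name] = s
        pset = dataclasses.replace(table2, specs=specs).with_run(n_iterations=200)
        verdict = viability_verdict(run_monte_carlo(pset), pset)
        assert verdict["irr_hurdle"]["passed"]
        assert verdict["breakeven_by_year"]["passed"]
        assert verdict["median_scenario_npv"]["passed"]
        assert verdict["overall"] is True

    def test_reports_measured_values_and_thresholds(self, mc_result, table2):
        verdict = viability_verdict(mc_result, table2, ViabilityCriteria())
        assert set(verdict) == {"irr_hurdle", "breakeven_by_year", "median_scenario_npv", "overall"}
        assert verdict["breakeven_by_year"]["year_limit"] == 5
        assert isinstance(verdict["irr_hurdle"]["measured"], float)
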