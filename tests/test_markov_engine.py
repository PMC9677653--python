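"""Cohort engine: transition matrices, traces, accrual, microsim oracle."""

from dataclasses import replace

import numpy as np
import pytest

from dialysis_cea.markov_engine import (
    CohortTrace,
    accrue,
    build_matrix,
    discount_factor,
    evaluate_strategy,
    microsimulate,
    run_cohort,
)
from dialysis_cea.param_model import (
    DEATH_INDEX,
    STATE_INDEX,
    AnalysisConfig,
    HealthState,
    ParameterError,
    sample_parameters,
)

from conftest import constant_mortality, make_simple_params


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "cycle,rate,expected",
        [(0, 0.03, 1.0), (1, 0.03, 1 / 1.03), (10, 0.0, 1.0), (2, 0.03, 1 / 1.03**2)],
    )
    def test_closed_form(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected, abs=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            discount_factor(1, -0.01)


class TestBuildMatrix:
    def test_identity_without_mortality_or_transitions(self):
        params = make_simple_params()
        mat = build_matrix(params.transitions["PD"], constant_mortality(0.0), 50.0, 0)
        assert np.allclose(mat, np.eye(5), atol=1e-12)

    def test_pd_row_death_first_composition(self):
        # death 0.1 resolved first; switch 0.039 and chronic onset 0.162 on survivors
        params = make_simple_params(p_switch=0.039, p_pd_cc=0.162)
        mat = build_matrix(params.transitions["PD"], constant_mortality(0.1), 50.0, 0)
        i = STATE_INDEX[HealthState.PD]
        assert mat[i, STATE_INDEX[HealthState.PD]] == pytest.approx(0.7191, abs=1e-12)
        assert mat[i, STATE_INDEX[HealthState.HD]] == pytest.approx(0.0351, abs=1e-12)
        assert mat[i, STATE_INDEX[HealthState.PD_CC]] == pytest.approx(0.1458, abs=1e-12)
        assert mat[i, DEATH_INDEX] == pytest.approx(0.1, abs=1e-12)
        assert mat[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one_for_random_draws(self, params, mortality):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            draw = sample_parameters(params, rng)
            stratum = "PD" if rng.random() < 0.5 else "HD"
            mat = build_matrix(
                draw.transitions[stratum], mortality[stratum], rng.uniform(20, 80), rng.integers(0, 30)
            )
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((mat >= 0) & (mat <= 1))
            # forbidden: chronic -> complication-free of the same modality; death absorbing
            assert mat[STATE_INDEX[HealthState.PD_CC], STATE_INDEX[HealthState.PD]] == 0
            assert mat[STATE_INDEX[HealthState.HD_CC], STATE_INDEX[HealthState.HD]] == 0
            assert np.array_equal(mat[DEATH_INDEX], [0, 0, 0, 0, 1])

    def test_competing_probabilities_renormalised(self, caplog):
        params = make_simple_params(p_switch=0.7, p_pd_cc=0.6)
        with caplog.at_level("WARNING"):
            mat = build_matrix(params.transitions["PD"], constant_mortality(0.1), 50.0, 0)
        assert "renormalising" in caplog.text
        assert mat[0].sum() == pytest.approx(1.0, abs=1e-12)
        assert mat[0, 0] == pytest.approx(0.0, abs=1e-12)  # no stay mass left


class TestRunCohort:
    def test_constant_hazard_geometric_occupancy(self):
        q = 0.2
        params = make_simple_params()
        cfg = AnalysisConfig(start_age=60.0, age_cap=80.0)
        trace = run_cohort(params, constant_mortality(q), cfg, "PD")
        for t in range(trace.n_cycles + 1):
            assert trace.occupancy[t, 0] == pytest.approx((1 - q) ** t, abs=1e-12)

    def test_mass_conserved_and_death_monotone(self, params, mortality, config):
        for strategy in ("PD", "HD"):
            trace = run_cohort(params, mortality[strategy], config, strategy)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(np.diff(trace.occupancy[:, DEATH_INDEX]) >= -1e-15)
            assert trace.occupancy[0, STATE_INDEX[HealthState[strategy]]] == 1.0

    def test_runs_until_extinction_or_age_cap(self, params, mortality, config):
        trace = run_cohort(params, mortality["PD"], config, "PD")
        assert (
            trace.living_mass()[-1] < config.living_mass_tol
            or trace.n_cycles == int(np.ceil(config.age_cap - config.start_age))
        )


class TestAccrue:
    def test_no_deaths_unit_utility_r0(self):
        params = make_simple_params(utility=1.0)
        cfg = AnalysisConfig(discount_rate=0.0, start_age=50.0, age_cap=60.0)
        trace = run_cohort(params, constant_mortality(0.0), cfg, "PD")
        out = accrue(trace, params, cfg)
        assert out.life_years == pytest.approx(10.0, abs=1e-10)
        assert out.qalys == pytest.approx(10.0, abs=1e-10)
        assert out.lifetime_cost == 0.0

    def test_three_cycle_annuity(self):
        C = 1234.5
        params = make_simple_params(annual_cost=C)
        cfg = AnalysisConfig(discount_rate=0.03, start_age=50.0, age_cap=53.0)
        trace = run_cohort(params, constant_mortality(0.0), cfg, "PD")
        out = accrue(trace, params, cfg)
        assert out.lifetime_cost == pytest.approx(C * (1 + 1 / 1.03 + 1 / 1.03**2), abs=1e-8)

    def test_all_dead_trace_accrues_nothing(self):
        params = make_simple_params(annual_cost=100.0, setup=0.0)
        occ = np.zeros((4, 5))
        occ[:, DEATH_INDEX] = 1.0
        trace = CohortTrace(
            occupancy=occ,
            strategy="PD",
            start_age=50.0,
            switch_to_pd=np.zeros(3),
            switch_to_hd=np.zeros(3),
        )
        out = accrue(trace, params, AnalysisConfig())
        assert out.life_years == 0.0 and out.qalys == 0.0 and out.lifetime_cost == 0.0

    def test_perspective_decomposition(self, params, mortality, config):
        """Societal minus government equals the non-medical + indirect streams."""
        import copy

        cfg_g = replace(config, perspective="government")
        cfg_s = replace(config, perspective="societal")
        zeroed = copy.deepcopy(params)
        for group in (zeroed.costs.annual_direct_nonmedical, zeroed.costs.annual_indirect):
            for est in group.values():
                est.mean = 0.0
                est.low = est.high = None
                est.dist = "fixed"
                est._cache_dist_params()
        for strategy in ("PD", "HD"):
            trace = run_cohort(params, mortality[strategy], cfg_s, strategy)
            gov = accrue(trace, params, cfg_g)
            soc_zeroed = accrue(trace, zeroed, cfg_s)
            assert soc_zeroed.lifetime_cost == pytest.approx(gov.lifetime_cost, rel=1e-12)
            soc = accrue(trace, params, cfg_s)
            assert soc.lifetime_cost > gov.lifetime_cost

    def test_qalys_bounded_by_life_years(self, params, mortality, config):
        for strategy in ("PD", "HD"):
            _, out = evaluate_strategy(params, mortality[strategy], config, strategy)
            assert 0.0 < out.qalys <= out.life_years

    def test_monotonicity_in_utility_cost_and_discount(self, params, mortality, config):
        _, base = evaluate_strategy(params, mortality["PD"], config, "PD")
        up_util = params.with_mean("utilities.PD", 0.80)
        _, out = evaluate_strategy(up_util, mortality["PD"], config, "PD")
        assert out.qalys > base.qalys
        up_cost = params.with_mean("costs.annual_direct_medical.PD", 9000.0)
        _, out = evaluate_strategy(up_cost, mortality["PD"], config, "PD")
        assert out.lifetime_cost > base.lifetime_cost
        cfg_hi_r = replace(config, discount_rate=0.05)
        _, out = evaluate_strategy(params, mortality["PD"], cfg_hi_r, "PD")
        assert out.lifetime_cost < base.lifetime_cost
        assert out.qalys < base.qalys
        assert out.life_years < base.life_years


class TestMicrosimOracle:
    def test_cohort_engine_matches_microsimulation(self, params, mortality, config):
        """Expected outcomes equal the individual-level simulation within MC error."""
        cfg = replace(config, start_age=60.0)
        rng = np.random.default_rng(1)
        outs = microsimulate(params, mortality["PD"], cfg, "PD", 20_000, rng)
        _, det = evaluate_strategy(params, mortality["PD"], cfg, "PD")
        for attr in ("lifetime_cost", "life_years", "qalys"):
            vals = np.array([getattr(o, attr) for o in outs])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - getattr(det, attr)) < 4 * se, attr
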