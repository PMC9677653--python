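"""ICER, deterministic tables, tornado, PSA and acceptability curves."""

from dataclasses import replace

import numpy as np
import pytest

from dialysis_cea.cea_analysis import (
    CEACCurve,
    PSAResult,
    ceac,
    crossover_wtp,
    deterministic_table,
    icer,
    run_psa,
    tornado,
)
from dialysis_cea.param_model import ParameterError

from conftest import constant_mortality, make_simple_params


class TestICER:
    def test_published_age60_government_cell(self):
        res = icer(37_837, 2.94, 58_243, 3.99)
        assert round(res.value) == 19_434

    def test_published_age20_societal_cell(self):
        res = icer(96_355, 6.43, 166_600, 8.19)
        assert round(res.value) == 39_912

    def test_dominance_labels(self):
        assert icer(100.0, 1.0, 50.0, 2.0).label == "dominant"
        assert icer(100.0, 2.0, 150.0, 1.0).label == "dominated"
        assert icer(100.0, 1.0, 150.0, 2.0).label == "icer"

    def test_zero_qaly_difference_undefined(self):
        res = icer(100.0, 1.0, 150.0, 1.0)
        assert res.label == "undefined" and res.value is None
        assert res.delta_cost == 50.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            icer(np.nan, 1.0, 2.0, 3.0)


class TestDeterministicTable:
    def test_cost_per_ly_and_icer_internally_consistent(self, params, mortality, config):
        table = deterministic_table(params, mortality, config, ages=[40.0, 60.0])
        for row in table.itertuples():
            assert row.cost_per_ly_pd == pytest.approx(row.cost_pd / row.ly_pd)
            expected = icer(row.cost_pd, row.qaly_pd, row.cost_hd, row.qaly_hd)
            assert row.icer == pytest.approx(expected.value)

    def test_government_equals_societal_with_zeroed_streams(
        self, params, mortality, config
    ):
        import copy

        zeroed = copy.deepcopy(params)
        for group in (zeroed.costs.annual_direct_nonmedical, zeroed.costs.annual_indirect):
            for est in group.values():
                est.mean, est.low, est.high, est.dist = 0.0, None, None, "fixed"
                est._cache_dist_params()
        gov = deterministic_table(params, mortality, config, ages=[50.0], perspectives=["government"])
        soc0 = deterministic_table(zeroed, mortality, config, ages=[50.0], perspectives=["societal"])
        assert gov["cost_pd"].iloc[0] == pytest.approx(soc0["cost_pd"].iloc[0], rel=1e-12)
        assert gov["cost_hd"].iloc[0] == pytest.approx(soc0["cost_hd"].iloc[0], rel=1e-12)

    def test_zero_costs_zero_discount_gives_zero_icer(self):
        params = make_simple_params(p_switch=0.01, utility=0.8)
        mort = {"PD": constant_mortality(0.1), "HD": constant_mortality(0.05)}
        from dialysis_cea.param_model import AnalysisConfig

        cfg = AnalysisConfig(discount_rate=0.0, start_age=60.0, age_cap=100.0)
        table = deterministic_table(params, mort, cfg, ages=[60.0], perspectives=["societal"])
        assert table["icer"].iloc[0] == pytest.approx(0.0)


class TestTornado:
    def test_fixed_parameter_has_zero_span(self, mortality, config):
        params = make_simple_params(
            p_switch=0.01, annual_cost=5000.0, utility=0.7
        )
        mort = {"PD": constant_mortality(0.12), "HD": constant_mortality(0.08)}
        table = tornado(params, mort, config)
        assert (table["span"] == 0.0).all()

    def test_sorted_by_descending_span(self, params, mortality, config):
        table = tornado(params, mortality, config)
        spans = table.loc[table["defined"], "span"].to_numpy()
        assert np.all(np.diff(spans) <= 1e-9)

    def test_base_icer_within_extreme_entries(self, params, mortality, config):
        table = tornado(params, mortality, config)
        base = table.attrs["base_icer"]
        top = table.iloc[0]
        assert min(top.icer_at_low, top.icer_at_high) <= base <= max(
            top.icer_at_low, top.icer_at_high
        )


class TestPSA:
    def test_all_fixed_distributions_reproduce_deterministic(self, params, mortality, config):
        import copy

        fixed = copy.deepcopy(params)
        for _, est in fixed.iter_estimates():
            est.dist = "fixed"
            est._cache_dist_params()
        cfg = replace(config, psa_iterations=5, seed=1)
        psa = run_psa(fixed, mortality, cfg)
        det = deterministic_table(
            params, mortality, config, ages=[config.start_age], perspectives=[config.perspective]
        ).iloc[0]
        assert np.allclose(psa.costs[:, 0], det.cost_pd)
        assert np.allclose(psa.qalys[:, 1], det.qaly_hd)

    def test_mean_difference_linearity(self, params, mortality, config):
        cfg = replace(config, psa_iterations=50, seed=5)
        psa = run_psa(params, mortality, cfg)
        s = psa.summary()
        assert s["mean_cost_diff"] == pytest.approx(
            s["mean_cost_hd"] - s["mean_cost_pd"], abs=1e-9
        )
        assert s["mean_qaly_diff"] == pytest.approx(
            s["mean_qaly_hd"] - s["mean_qaly_pd"], abs=1e-12
        )

    def test_seed_reproducibility(self, params, mortality, config):
        cfg = replace(config, psa_iterations=20, seed=11)
        a = run_psa(params, mortality, cfg)
        b = run_psa(params, mortality, cfg)
        assert np.array_equal(a.costs, b.costs) and np.array_equal(a.qalys, b.qalys)

    def test_bootstrap_se_positive(self, params, mortality, config):
        cfg = replace(config, psa_iterations=50, seed=5)
        ses = run_psa(params, mortality, cfg).bootstrap_se(n_boot=100)
        assert ses["se_mean_cost_diff"] > 0 and ses["se_mean_qaly_diff"] > 0


def _toy_psa(delta_costs, delta_qalys):
    n = len(delta_costs)
    costs = np.column_stack([np.zeros(n), np.asarray(delta_costs, dtype=float)])
    qalys = np.column_stack([np.zeros(n), np.asarray(delta_qalys, dtype=float)])
    return PSAResult(costs=costs, qalys=qalys, seed=0, perspective="societal", start_age=55.7)


class TestCEAC:
    def test_probabilities_partition_unity(self, params, mortality, config):
        cfg = replace(config, psa_iterations=40, seed=2)
        curve = ceac(run_psa(params, mortality, cfg))
        assert np.allclose(curve.prob_pd + curve.prob_hd, 1.0, atol=1e-12)

    def test_zero_wtp_is_cost_minimisation(self):
        psa = _toy_psa([-10, 5, 20, -3], [1, 1, 1, 1])
        curve = ceac(psa, wtp_grid=np.array([0.0]))
        assert curve.prob_hd[0] == pytest.approx(0.5)  # HD cheaper in 2 of 4 draws

    def test_large_wtp_driven_by_qalys(self):
        psa = _toy_psa([100.0] * 4, [1, 1, 1, -1])
        curve = ceac(psa, wtp_grid=np.array([1e9]))
        assert curve.prob_hd[0] == pytest.approx(0.75)

    def test_degenerate_draws_step_at_deterministic_icer(self):
        psa = _toy_psa([20_000.0] * 10, [1.0] * 10)
        curve = ceac(psa, wtp_grid=np.arange(0, 40_001, 100.0))
        below = curve.wtp < 20_000
        above = curve.wtp > 20_000
        assert np.all(curve.prob_hd[below] == 0.0)
        assert np.all(curve.prob_hd[above] == 1.0)

    def test_tie_split_equally(self):
        psa = _toy_psa([10_000.0], [1.0])
        curve = ceac(psa, wtp_grid=np.array([10_000.0]))
        assert curve.prob_hd[0] == pytest.approx(0.5)


class TestCrossover:
    def test_constructed_crossing_recovered(self):
        rng = np.random.default_rng(0)
        # ICER distribution symmetric around 20,000 -> median crossover there
        psa = _toy_psa(20_000.0 + rng.normal(0, 4000, 2001), np.ones(2001))
        curve = ceac(psa, wtp_grid=np.arange(0, 40_001, 100.0))
        assert crossover_wtp(curve) == pytest.approx(20_000, abs=300)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(1)
        psa = _toy_psa(15_000.0 + rng.normal(0, 3000, 1001), np.ones(1001))
        curve = ceac(psa, wtp_grid=np.arange(0, 30_001, 100.0))
        flipped = CEACCurve(wtp=curve.wtp, prob_pd=curve.prob_hd, prob_hd=curve.prob_pd)
        assert crossover_wtp(curve) == pytest.approx(crossover_wtp(flipped), abs=100)

    def test_dominant_strategy_has_no_crossing(self):
        psa = _toy_psa([-500.0] * 10, [1.0] * 10)  # HD dominant in every draw
        curve = ceac(psa, wtp_grid=np.arange(0, 10_001, 100.0))
        assert crossover_wtp(curve) is None
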