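import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers_oracle import microsimulate
from t2dscreen.markov import (ALIVE, HealthState, ModelConfig, accumulate,
                              adjust_probability, build_transition_row,
                              evaluate_strategy, hba1c_multiplier,
                              mortality_rr, run_cohort, simpson_weights,
                              state_mortality, transition_matrix,
                              undx_comp_probability, utility_vector)
from t2dscreen.screening import ScreeningStrategy
from t2dscreen.synthetic_data import LifeTable


class TestAdjustProbability:
    def test_reproduces_tabulated_complication_probability(self, params):
        rr = hba1c_multiplier(1.40, 8.5, 7.0)
        assert round(adjust_probability(0.0140, rr), 4) == 0.0231

    def test_identity(self):
        assert adjust_probability(0.37, 1.0) == pytest.approx(0.37)

    def test_closed_form(self):
        assert adjust_probability(0.5, 2.0) == pytest.approx(0.75)

    def test_p_one_rejected(self):
        with pytest.raises(ValueError):
            adjust_probability(1.0, 2.0)

    @given(p=st.floats(0.0, 0.99), rr=st.floats(0.1, 5.0))
    def test_stays_in_unit_interval(self, p, rr):
        q = adjust_probability(p, rr)
        assert 0.0 <= q < 1.0
        if rr > 1.0:
            assert q >= p - 1e-15  # fp roundoff near p = 0


class TestHba1cMultiplier:
    def test_complication_example(self):
        assert hba1c_multiplier(1.40, 8.5, 7.0) == pytest.approx(1.6565, abs=1e-4)

    def test_identity_at_reference(self):
        assert hba1c_multiplier(1.38, 7.0, 7.0) == 1.0

    def test_mortality_example(self):
        assert hba1c_multiplier(1.38, 9.1, 7.0) == pytest.approx(1.967, abs=1e-3)


class TestStateMortality:
    def test_ngt_is_background(self, params):
        assert state_mortality(0.01, HealthState.NGT, params) == 0.01

    def test_undx_composition(self, params):
        got = state_mortality(0.01, HealthState.UNDX, params)
        rr = 1.89 * hba1c_multiplier(1.38, 8.5, 7.0)
        assert got == pytest.approx(adjust_probability(0.01, rr))
        assert got == pytest.approx(0.03033, abs=1e-5)

    def test_monotone_across_states(self, params):
        for qx in (0.001, 0.01, 0.05, 0.2):
            ngt = state_mortality(qx, HealthState.NGT, params)
            dx = state_mortality(qx, HealthState.DX, params)
            undx = state_mortality(qx, HealthState.UNDX, params)
            comp = state_mortality(qx, HealthState.COMP, params)
            assert comp >= undx >= dx >= ngt

    def test_derived_complication_probability(self, params):
        assert round(undx_comp_probability(params), 4) == 0.0231


class TestTransitionRows:
    def test_dead_absorbing(self, params, life_table):
        row = build_transition_row(HealthState.DEAD, 50, False, None, params,
                                   life_table)
        assert np.array_equal(row, [0, 0, 0, 0, 1])

    def test_rows_sum_to_one_everywhere(self, params, life_table):
        from t2dscreen.screening import misclassification_outcomes
        strat = ScreeningStrategy(setting="CHS", interval="annual", start_age=30)
        cascade = misclassification_outcomes(strat, params)
        for age in range(30, 100):
            for screened in (False, True):
                mat = transition_matrix(age, screened, cascade, params, life_table)
                assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(mat >= 0.0)

    def test_screened_undx_exit_union(self, params, life_table):
        from t2dscreen.screening import misclassification_outcomes
        strat = ScreeningStrategy(setting="CHS", interval="annual", start_age=40)
        cascade = misclassification_outcomes(strat, params)
        row = build_transition_row(HealthState.UNDX, 40, True, cascade, params,
                                   life_table)
        death = state_mortality(life_table.q(40), HealthState.UNDX, params)
        p_detect = cascade.p_detect_given_diseased
        expected = (1.0 - death) * (1.0 - (1.0 - 0.0352) * (1.0 - p_detect))
        assert row[HealthState.DX] == pytest.approx(expected, abs=1e-12)

    def test_exit_rescaling_logged(self, params, life_table, caplog):
        crowded = dataclasses.replace(params, p_undx_dx=0.95, hba1c_undx=14.0)
        with caplog.at_level("WARNING"):
            row = build_transition_row(HealthState.UNDX, 40, False, None,
                                       crowded, life_table)
        assert row.sum() == pytest.approx(1.0)
        assert np.all(row >= 0.0)


class TestRunCohort:
    def test_mass_conserved_and_dead_monotone(self, params, life_table,
                                              all_strategies):
        for strat in [None] + all_strategies:
            cfg = ModelConfig(start_age=40, strategy=strat)
            trace = run_cohort(cfg, params, life_table)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diff(trace.occupancy[:, HealthState.DEAD]) >= -1e-15)

    def test_matches_public_transition_rows(self, params, life_table):
        # the optimized inner loop must agree with the public row builder
        from t2dscreen.screening import misclassification_outcomes
        strat = ScreeningStrategy(setting="DHC", interval="3-yearly", start_age=40)
        cascade = misclassification_outcomes(strat, params)
        cfg = ModelConfig(start_age=40, strategy=strat)
        trace = run_cohort(cfg, params, life_table)
        n = cfg.max_age - cfg.start_age
        cycles = strat.screening_cycles(n)
        v = trace.occupancy[0]
        for t in range(n):
            mat = transition_matrix(40 + t, t in cycles, cascade, params,
                                    life_table)
            v = v @ mat
            assert np.allclose(v, trace.occupancy[t + 1], atol=1e-13)

    def test_frozen_cohort(self, life_table, params):
        frozen = dataclasses.replace(
            params, p_ngt_undx=0.0, p_ngt_dx=0.0, p_undx_dx=0.0, p_dx_comp=0.0,
            hba1c_undx=7.0, hba1c_comp=7.0, rr_death_t2dm=1.0,
            rr_death_per_hba1c=1.0)
        tiny_q = LifeTable(ages=np.arange(101),
                           qx=np.append(np.full(100, 1e-12), 1.0))
        cfg = ModelConfig(start_age=40)
        trace = run_cohort(cfg, frozen, tiny_q)
        assert np.allclose(trace.occupancy[-1], trace.occupancy[0], atol=1e-9)

    def test_everyone_dies_first_cycle_hand_calc(self, params):
        lethal = LifeTable(ages=np.arange(43), qx=np.ones(43))
        cfg = ModelConfig(start_age=40, max_age=42, discount_rate=0.0)
        trace = run_cohort(cfg, params, lethal)
        assert trace.occupancy[1, HealthState.DEAD] == 1.0
        out = accumulate(trace, params, cfg)
        # Simpson weights (1/3, 4/3, 1/3): only cycle 0 is alive
        assert out.total_ly == pytest.approx(1.0 / 3.0)
        prev = params.prevalence_for(40)
        expected_qaly = (1.0 / 3.0) * ((1.0 - prev) * params.u_ngt
                                       + prev * params.u_undx)
        assert out.total_qaly == pytest.approx(expected_qaly)

    def test_short_life_table_rejected(self, params):
        short = LifeTable(ages=np.arange(60), qx=np.append(np.full(59, 0.01), 1.0))
        with pytest.raises(ValueError):
            run_cohort(ModelConfig(start_age=40), params, short)

    def test_trace_export_schema(self, params, life_table):
        cfg = ModelConfig(start_age=40,
                          strategy=ScreeningStrategy(setting="CHS",
                                                     interval="annual",
                                                     start_age=40))
        df = run_cohort(cfg, params, life_table).to_frame()
        assert list(df.columns[:7]) == ["cycle", "age", "ngt", "undx", "dx",
                                        "comp", "dead"]
        assert df["age"].iloc[0] == 40 and df["age"].iloc[-1] == 100

    def test_small_microsimulation_parity(self, params, life_table):
        strat = ScreeningStrategy(setting="CHS", interval="annual", start_age=40)
        cfg = ModelConfig(start_age=40, strategy=strat)
        trace = run_cohort(cfg, params, life_table)
        n_persons = 20000
        occ = microsimulate(n_persons, cfg, params, life_table, seed=123)
        se = np.sqrt(trace.occupancy * (1.0 - trace.occupancy) / n_persons)
        # small count floor covers Poisson tails in near-empty cells at this n
        assert np.all(np.abs(occ - trace.occupancy) <= 3.0 * se + 3.0 / n_persons)


class TestSimpson:
    def test_two_intervals(self):
        assert np.allclose(simpson_weights(2), [1 / 3, 4 / 3, 1 / 3])

    def test_four_intervals(self):
        assert np.allclose(simpson_weights(4), [1 / 3, 4 / 3, 2 / 3, 4 / 3, 1 / 3])

    def test_three_intervals_uses_three_eighths(self):
        assert np.allclose(simpson_weights(3), np.array([3, 9, 9, 3]) / 8.0)

    @given(n=st.integers(2, 200))
    def test_weights_sum_to_interval_count(self, n):
        assert simpson_weights(n).sum() == pytest.approx(n, abs=1e-10)

    def test_exact_for_quadratic(self):
        t = np.arange(5.0)
        assert np.dot(simpson_weights(4), t ** 2) == pytest.approx(64.0 / 3.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 7, 10, 60])
    def test_exact_for_cubics(self, n):
        t = np.arange(n + 1.0)
        assert np.dot(simpson_weights(n), t ** 3) == pytest.approx(
            n ** 4 / 4.0, rel=1e-12)

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            simpson_weights(1)


class TestAccumulate:
    def test_all_utilities_one_gives_ly(self, params, life_table):
        ideal = dataclasses.replace(params, u_ngt=1.0, u_undx=1.0, u_dx=1.0,
                                    u_comp=1.0)
        cfg = ModelConfig(start_age=40)
        trace = run_cohort(cfg, ideal, life_table)
        out = accumulate(trace, ideal, cfg)
        assert out.total_qaly == pytest.approx(out.total_ly, abs=1e-12)

    def test_cost_homogeneity(self, params, life_table):
        cfg = ModelConfig(start_age=40,
                          strategy=ScreeningStrategy(setting="CHS",
                                                     interval="annual",
                                                     start_age=40))
        trace = run_cohort(cfg, params, life_table)
        base = accumulate(trace, params, cfg)
        doubled = dataclasses.replace(
            params,
            **{f: 2.0 * getattr(params, f)
               for f in ("cost_tx_dx_med", "cost_tx_undx_med",
                         "cost_tx_comp_med", "cost_tx_dx_nonmed",
                         "cost_tx_undx_nonmed", "cost_tx_comp_nonmed")})
        out = accumulate(trace, doubled, cfg)
        assert out.treatment_cost == pytest.approx(2.0 * base.treatment_cost)
        assert out.screening_cost == pytest.approx(base.screening_cost)

    def test_components_sum(self, params, life_table):
        outs = evaluate_strategy(
            ScreeningStrategy(setting="DHC", interval="annual", start_age=40),
            40, params, life_table)
        for o in outs.values():
            assert o.total_cost == pytest.approx(o.screening_cost
                                                 + o.treatment_cost)
            assert o.total_qaly <= o.total_ly

    def test_discount_monotone(self, params, life_table):
        totals = []
        for r in (0.0, 0.03, 0.06):
            cfg = ModelConfig(start_age=40, discount_rate=r)
            trace = run_cohort(cfg, params, life_table)
            totals.append(accumulate(trace, params, cfg))
        assert totals[0].total_qaly > totals[1].total_qaly > totals[2].total_qaly
        assert totals[0].total_cost > totals[1].total_cost > totals[2].total_cost

    def test_screening_never_reduces_ly(self, params, life_table,
                                        all_strategies):
        base = evaluate_strategy(None, 40, params, life_table)["societal"]
        for strat in all_strategies:
            out = evaluate_strategy(strat, 40, params, life_table)["societal"]
            assert out.total_ly >= base.total_ly - 1e-9
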