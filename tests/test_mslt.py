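import numpy as np
import pandas as pd
import pytest

from cvdshock import InputError
from cvdshock._common import ETHNICITIES, SEXES
from cvdshock.mslt import (
    EconomicConfig,
    apply_trends,
    diff_outputs,
    discount_factor,
    disease_step,
    run_analysis,
    run_cohort,
)
from helpers import constant_rate_bundle, three_state_microsim


class TestDiseaseStep:
    def test_no_inflow_decays_through_fatality(self):
        state = (0.8, 0.2, 0.0)
        for _ in range(10):
            state = disease_step(state, i=0.0, f=0.1)
        h, c, d = state
        assert h == pytest.approx(0.8)
        assert c == pytest.approx(0.2 * 0.9**10)
        assert h + c + d == pytest.approx(1.0)

    def test_single_step_bookkeeping(self):
        h, c, d = disease_step((1.0, 0.0, 0.0), i=0.01, f=0.0)
        assert c == pytest.approx(0.01)
        assert d == 0.0

    def test_proportions_sum_to_one(self):
        state = (0.9, 0.1, 0.0)
        for _ in range(50):
            state = disease_step(state, i=0.02, f=0.05)
            assert sum(state) == pytest.approx(1.0)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(InputError):
            disease_step((1.0, 0.0, 0.0), i=1.0, f=0.0)
        with pytest.raises(InputError):
            disease_step((1.0, 0.0, 0.0), i=0.1, f=-0.1)

    def test_against_three_state_chain_microsim(self):
        i, f, cycles = 0.02, 0.06, 25
        state = (1.0, 0.0, 0.0)
        det = [0.0]
        for _ in range(cycles):
            state = disease_step(state, i=i, f=f)
            det.append(state[1])
        reps = [three_state_microsim(20_000, cycles, i, f, seed=100 + s) for s in range(16)]
        sim = np.mean(reps, axis=0)
        se = np.std(reps, axis=0, ddof=1) / np.sqrt(len(reps))
        for t in (1, 5, 12, 25):  # a few decorrelated checkpoints
            assert abs(det[t] - sim[t]) <= 3 * se[t]


class TestTrends:
    def test_cycle_zero_is_identity(self, bundle):
        out = apply_trends(bundle.epi, 0)
        pd.testing.assert_frame_equal(out.table, bundle.epi.table)

    def test_maori_mortality_two_cycles(self, bundle):
        out = apply_trends(bundle.epi, 2)
        base = bundle.epi.table
        mask = base.ethnicity == "maori"
        assert np.allclose(
            out.table.loc[mask, "acm"], base.loc[mask, "acm"] * 0.9775**2, rtol=1e-12
        )

    def test_mortality_trend_freezes_after_horizon(self, bundle):
        at15 = apply_trends(bundle.epi, 15).table["acm"]
        at20 = apply_trends(bundle.epi, 20).table["acm"]
        assert np.array_equal(at15, at20)

    def test_disease_trend_two_percent(self, bundle):
        out = apply_trends(bundle.epi, 3)
        assert np.allclose(
            out.table["chd_incidence"],
            bundle.epi.table["chd_incidence"] * 0.98**3,
            rtol=1e-12,
        )

    def test_frozen_disease_trend(self, bundle):
        from dataclasses import replace

        from cvdshock.synthetic_data import EpiTable

        frozen = EpiTable(
            table=bundle.epi.table,
            trends=replace(bundle.epi.trends, disease_trend_frozen=True),
        )
        out = apply_trends(frozen, 10)
        assert np.array_equal(out.table["chd_incidence"], bundle.epi.table["chd_incidence"])

    def test_negative_cycle_rejected(self, bundle):
        with pytest.raises(InputError):
            apply_trends(bundle.epi, -1)


class TestDiscounting:
    def test_closed_form(self):
        assert discount_factor(10, 0.03) == pytest.approx(1.03**-10)
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(5, 0.0) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(InputError):
            EconomicConfig(discount_rate=-0.01)

    def test_bad_horizon_rejected(self):
        with pytest.raises(InputError):
            EconomicConfig(horizons=(5, 0))


def _zero_risk_bundle():
    return constant_rate_bundle(
        m_bg=0.0, i_chd=0.0, f_chd=0.0, i_str=0.0, f_str=0.0,
        p0_chd=0.0, p0_str=0.0, start_age=60, count=100.0,
    )


class TestRunCohort:
    def test_conservation_limit_zero_risk(self):
        # no mortality, incidence, disability or discounting:
        # HALYs = population x years to the terminal age, exactly
        run = run_cohort(_zero_risk_bundle(), econ=EconomicConfig(discount_rate=0.0))
        total = run.cumulative("haly").sum()
        assert total == pytest.approx(100.0 * (110 - 60), rel=1e-12)

    def test_discounted_accrual_closed_form(self):
        run = run_cohort(_zero_risk_bundle(), econ=EconomicConfig(discount_rate=0.03))
        per_cycle = run.haly.sum(axis=1)
        expected = np.zeros(110)
        expected[:50] = 100.0 * 1.03 ** (-np.arange(50, dtype=float))
        assert np.allclose(per_cycle, expected, rtol=1e-12)

    def test_deterministic(self, bundle):
        r1 = run_cohort(bundle)
        r2 = run_cohort(bundle)
        assert np.array_equal(r1.alive, r2.alive)
        assert np.array_equal(r1.haly, r2.haly)
        assert np.array_equal(r1.cost, r2.cost)

    def test_state_conservation_each_cycle(self, base_case_result):
        run = base_case_result.baseline_run
        cum_dead = np.cumsum(run.deaths, axis=0)
        initial = run.initial
        for t in (1, 10, 50, 110):
            balance = run.alive[t] + cum_dead[t - 1]
            assert np.allclose(balance, initial, atol=1e-9)

    def test_alive_non_increasing_and_prevalence_bounded(self, base_case_result):
        run = base_case_result.scenario_run
        assert (np.diff(run.alive, axis=0) <= 1e-12).all()
        assert (run.chd_prevalent <= run.alive + 1e-12).all()
        assert (run.stroke_prevalent <= run.alive + 1e-12).all()
        assert (run.alive >= 0).all()

    def test_cohort_extinct_by_terminal_age(self, base_case_result):
        run = base_case_result.baseline_run
        ages_at_end = run.age0 + 110
        assert np.allclose(run.alive[-1], 0.0)
        assert ages_at_end.min() >= 110


class TestDiffOutputs:
    def test_identical_runs_give_exact_zero(self, bundle):
        run = run_cohort(bundle)
        out = diff_outputs(run, run)
        assert (out["haly_change"] == 0).all()
        assert (out["cost_change"] == 0).all()

    def test_adverse_rr_gives_losses_everywhere(self, bundle):
        rows = [
            (t, e, s, b, 1.05)
            for t in range(5)
            for e in ETHNICITIES
            for s in SEXES
            for b in ("35-44", "45-54", "55-64")
        ]
        rr = pd.DataFrame(rows, columns=["cycle", "ethnicity", "sex", "age_band", "rr"])
        out = diff_outputs(run_cohort(bundle, rr), run_cohort(bundle))
        lifetime = out[out.horizon == "lifetime"]
        assert (lifetime["haly_change"] <= 0).all()

    def test_horizon_magnitudes_monotone(self, bundle):
        rows = [
            (t, e, s, b, 1.05)
            for t in range(5)
            for e in ETHNICITIES
            for s in SEXES
            for b in ("35-44", "45-54", "55-64")
        ]
        rr = pd.DataFrame(rows, columns=["cycle", "ethnicity", "sex", "age_band", "rr"])
        out = diff_outputs(run_cohort(bundle, rr), run_cohort(bundle))
        total = out[(out.ethnicity == "all")].set_index("horizon")["haly_change"]
        losses = [-total[h] for h in ("5", "10", "20", "lifetime")]
        assert losses == sorted(losses)
        assert losses[0] >= 0

    def test_mismatched_econ_rejected(self, bundle):
        a = run_cohort(bundle, econ=EconomicConfig(discount_rate=0.03))
        b = run_cohort(bundle, econ=EconomicConfig(discount_rate=0.06))
        with pytest.raises(InputError):
            diff_outputs(a, b)

    def test_per_1000_consistent_with_absolute(self, base_case_result):
        out = base_case_result.outputs
        ok = out["population"] > 0
        lhs = out.loc[ok, "haly_per_1000"] * out.loc[ok, "population"] / 1000.0
        assert np.allclose(lhs, out.loc[ok, "haly_change"], atol=1e-9)


class TestRunAnalysis:
    def test_unknown_scenario_rejected(self, bundle):
        with pytest.raises(InputError):
            run_analysis(bundle, "no_such_scenario")

    def test_equity_params_switch_runs(self, bundle):
        res = run_analysis(bundle, "base_case", equity_params=True)
        assert len(res.outputs) > 0

    def test_freeze_disease_trend_increases_burden(self, bundle):
        base = run_analysis(bundle, "base_case")
        frozen = run_analysis(bundle, "base_case", freeze_disease_trend=True)

        def loss(res):
            o = res.outputs
            return -float(
                o[(o.ethnicity == "all") & (o.horizon == "lifetime")]["haly_change"].iloc[0]
            )

        assert loss(frozen) > loss(base)
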