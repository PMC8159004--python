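import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdshock import InputError
from cvdshock.calibration import (
    RateWeights,
    band_populations,
    build_shock_series,
    derive_weights,
    disaggregate_full,
    disaggregate_one_axis,
    restrict_to_model_bands,
)
from cvdshock.synthetic_data import (
    UnemploymentConfig,
    generate_population,
    generate_unemployment_baseline,
)
from helpers import solve_axis_deltas


class TestDeriveWeights:
    def test_equal_rates_give_unit_weight(self, bundle):
        import copy

        base = copy.deepcopy(bundle.unemployment)
        base.ethnicity_rates["maori"] = base.ethnicity_rates["non_maori"]
        w = derive_weights(base)
        assert w.w_e == 1.0

    def test_direct_ratio(self, bundle):
        w = derive_weights(bundle.unemployment)
        assert w.w_e == pytest.approx(2.0, abs=1e-12)
        assert w.w_a["45-54"] == 1.0

    def test_zero_rate_rejected(self, bundle):
        import copy

        base = copy.deepcopy(bundle.unemployment)
        base.sex_rates["male"] = 0.0
        with pytest.raises(InputError):
            derive_weights(base)

    def test_weights_must_be_positive(self):
        with pytest.raises(InputError):
            RateWeights(w_e=-1.0, w_s=1.0, w_a={"45-54": 1.0})


class TestOneAxis:
    def test_equal_rates_symmetry(self):
        deltas = disaggregate_one_axis(0.01, [(100.0, 0.05), (900.0, 0.05)])
        assert deltas == pytest.approx([0.01, 0.01])

    def test_two_group_worked_example(self):
        # pop 100/900 at rates 0.08/0.04, aggregate +0.01:
        # dU_g = dU * U_g * N / sum(pop*U) with sum(pop*U) = 8 + 36 = 44
        deltas = disaggregate_one_axis(0.01, [(100.0, 0.08), (900.0, 0.04)])
        assert deltas[0] == pytest.approx(0.01 * 0.08 * 1000 / 44)  # ~0.0181818
        assert deltas[1] == pytest.approx(0.01 * 0.04 * 1000 / 44)  # ~0.0090909
        assert deltas[1] == pytest.approx(10.0 / 1100.0)

    def test_matches_linear_system_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(2, 6)
            pops = rng.uniform(10, 1000, n)
            rates = rng.uniform(0.01, 0.3, n)
            du = rng.uniform(-0.02, 0.05)
            got = disaggregate_one_axis(du, list(zip(pops, rates)))
            want = solve_axis_deltas(du, pops, rates)
            assert np.allclose(got, want, rtol=1e-10)

    def test_round_trip_weights_preserved(self):
        pops, rates = [200.0, 800.0], [0.09, 0.03]
        deltas = disaggregate_one_axis(0.02, list(zip(pops, rates)))
        shifted = [r + d for r, d in zip(rates, deltas)]
        assert shifted[0] / shifted[1] == pytest.approx(rates[0] / rates[1], rel=1e-12)

    def test_all_zero_population_rejected(self):
        with pytest.raises(InputError):
            disaggregate_one_axis(0.01, [(0.0, 0.05), (0.0, 0.04)])

    def test_zero_rate_rejected(self):
        with pytest.raises(InputError):
            disaggregate_one_axis(0.01, [(10.0, 0.0), (10.0, 0.04)])

    @given(
        du=st.floats(-0.02, 0.05),
        pops=st.lists(st.floats(1.0, 1e5), min_size=2, max_size=5),
        rates=st.lists(st.floats(0.005, 0.4), min_size=5, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_homogeneity(self, du, pops, rates):
        groups = list(zip(pops, rates[: len(pops)]))
        deltas = np.array(disaggregate_one_axis(du, groups))
        p = np.array(pops)
        assert float(p @ deltas / p.sum()) == pytest.approx(du, abs=1e-10)
        doubled = np.array(disaggregate_one_axis(2.0 * du, groups))
        assert np.allclose(doubled, 2.0 * deltas, rtol=1e-12, atol=1e-18)


@pytest.fixture(scope="module")
def pop():
    return generate_population(seed=11)


class TestFullDisaggregation:
    def test_flat_rates_give_uniform_deltas(self, pop):
        cfg = UnemploymentConfig(maori_ratio=1.0, female_male_ratio=1.0, age_gradient=False)
        base = generate_unemployment_baseline(cfg, pop)
        deltas = disaggregate_full(0.02, pop, base, year=2020)
        assert np.allclose(deltas["du"], 0.02, rtol=1e-12)

    def test_weighted_mean_conservation(self, pop, bundle):
        deltas = disaggregate_full(0.037, pop, bundle.unemployment, year=2021)
        pops = band_populations(pop)
        merged = pops.merge(deltas, on=["ethnicity", "sex", "age_band"])
        mean = (merged["count"] * merged["du"]).sum() / merged["count"].sum()
        assert mean == pytest.approx(0.037, abs=1e-10)

    def test_ethnic_delta_ratio_matches_weight(self, pop, bundle):
        w = derive_weights(bundle.unemployment)
        deltas = disaggregate_full(0.03, pop, bundle.unemployment, year=2021)
        piv = deltas.pivot_table(
            index=["sex", "age_band"], columns="ethnicity", values="du"
        )
        assert np.allclose(piv["maori"] / piv["non_maori"], w.w_e, rtol=1e-10)

    def test_homogeneity(self, pop, bundle):
        d1 = disaggregate_full(0.01, pop, bundle.unemployment, year=2021)
        d2 = disaggregate_full(0.03, pop, bundle.unemployment, year=2021)
        assert np.allclose(d2["du"], 3.0 * d1["du"], rtol=1e-12)

    def test_restriction_to_model_bands(self, pop, bundle):
        deltas = disaggregate_full(0.02, pop, bundle.unemployment, year=2021)
        assert set(deltas["age_band"]) == {"15-24", "25-34", "35-44", "45-54", "55-64"}
        restricted = restrict_to_model_bands(deltas)
        assert set(restricted["age_band"]) == {"35-44", "45-54", "55-64"}

    def test_degenerate_shock_is_clipped_with_warning(self, pop, bundle, caplog):
        with caplog.at_level(logging.WARNING, logger="cvdshock.calibration"):
            deltas = disaggregate_full(0.5, pop, bundle.unemployment, year=2021)
        assert "clipping" in caplog.text
        base = bundle.unemployment.rates.set_index(["ethnicity", "sex", "age_band"])["rate"]
        keys = list(zip(deltas["ethnicity"], deltas["sex"], deltas["age_band"]))
        shifted = np.array([base.loc[k] for k in keys]) + deltas["du"].to_numpy()
        assert ((shifted >= 0) & (shifted <= 1 + 1e-12)).all()


class TestShockSeries:
    def test_series_covers_shock_cycles_only(self, bundle):
        shock = build_shock_series(
            bundle.population, bundle.unemployment, bundle.scenarios["base_case"]
        )
        assert set(shock["cycle"]) == {0, 1, 2, 3, 4}
        assert set(shock["age_band"]) == {"35-44", "45-54", "55-64"}

    def test_baseline_scenario_is_empty(self, bundle):
        shock = build_shock_series(
            bundle.population, bundle.unemployment, bundle.scenarios["baseline"]
        )
        assert len(shock) == 0

    def test_ten_year_duration_extends(self, bundle):
        shock = build_shock_series(
            bundle.population,
            bundle.unemployment,
            bundle.scenarios["base_case"],
            duration=10,
        )
        assert set(shock["cycle"]) == set(range(10))
        last5 = shock[shock["cycle"] == 5].set_index(["ethnicity", "sex", "age_band"])["du"]
        last9 = shock[shock["cycle"] == 9].set_index(["ethnicity", "sex", "age_band"])["du"]
        pd.testing.assert_series_equal(last5, last9)
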