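"""Scenario parameter paths: fertility, SRB, international migration,
life table and mortality inversion, internal migration rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import citypop.scenarios as sc
from citypop import (
    PopulationState,
    RateSet,
    ValidationError,
    birth_shares,
    le_target,
    life_expectancy,
    migration_rate_at,
    mortality_for_target,
    netgim_path,
    scale_asfr,
    srb_path,
    tfr_path,
)
from citypop.core import N_AGES, GeoHierarchy, Province, City


class TestTfrPath:
    @pytest.mark.parametrize(
        "fid,year,expected",
        [
            (3, 2050, 1.5),
            (1, 2050, 0.7),
            (5, 2050, 1.8),
            (1, 2100, 0.9),
            (3, 2100, 1.8),
            (5, 2100, 2.1),
            (2, 2035, 1.3),  # constant segment between equal anchors
            (4, 2013, 1.50),
            (4, 2017, 1.88),
        ],
    )
    def test_anchors(self, fid, year, expected):
        assert tfr_path(fid, year) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fid", range(1, 6))
    def test_shared_history_until_2020(self, fid):
        years = np.arange(2010, 2021)
        np.testing.assert_allclose(tfr_path(fid, years), tfr_path(2, years))
        assert tfr_path(fid, 2020) == pytest.approx(1.30)

    @pytest.mark.parametrize("fid", range(1, 6))
    def test_continuity(self, fid):
        vals = tfr_path(fid, np.arange(2010, 2111))
        # steepest anchor segment is the observed 2017 -> 2020 decline
        max_anchor_slope = (1.88 - 1.30) / (2020 - 2017)
        assert np.max(np.abs(np.diff(vals))) <= max_anchor_slope + 1e-12

    def test_constant_after_2100(self):
        assert tfr_path(5, 2150) == tfr_path(5, 2100)

    def test_unknown_scenario(self):
        with pytest.raises(ValidationError):
            tfr_path(0, 2050)


class TestSrbAndShares:
    def test_target_reached_and_held(self):
        assert srb_path(2050) == pytest.approx(1.07)
        assert srb_path(2080) == pytest.approx(1.07)
        assert srb_path(2010, baseline_srb=1.18) == pytest.approx(1.18)

    def test_linear_in_between(self):
        assert srb_path(2030, baseline_srb=1.18) == pytest.approx((1.18 + 1.07) / 2)

    def test_symmetric_shares(self):
        assert birth_shares(1.0) == pytest.approx((0.5, 0.5))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.5, max_value=2.0))
    def test_shares_sum_to_one(self, srb):
        bm, bf = birth_shares(srb)
        assert bm + bf == pytest.approx(1.0, abs=1e-12)
        assert bm / bf == pytest.approx(srb)


class TestNetgim:
    def test_constant_segment(self):
        assert netgim_path(2020) == pytest.approx(-3.015e-4)
        assert netgim_path(2050) == pytest.approx(-3.015e-4)

    def test_declines_to_zero(self):
        assert netgim_path(2100) == 0.0
        assert netgim_path(2075) == pytest.approx(-1.5075e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            netgim_path(2005)
        with pytest.raises(ValidationError):
            netgim_path(2101)


class TestScaleAsfr:
    def _world(self, tfrs, fpops):
        n = len(tfrs)
        asfr = np.zeros((n, 35))
        for i, t in enumerate(tfrs):
            asfr[i, 10] = t  # all fertility at age 25
        counts = np.zeros((n, 2, N_AGES))
        counts[:, 1, 25] = fpops
        cities = tuple(f"c{i}" for i in range(n))
        state = PopulationState(2010, cities, counts)
        rates = RateSet(
            cities, ("p",), asfr, np.zeros((n, 2, N_AGES)),
            np.zeros((n, 2, N_AGES)), np.zeros((1, 2, N_AGES)),
        )
        return state, rates

    def test_identity_and_doubling(self):
        state, rates = self._world([1.2, 1.8], [100.0, 100.0])
        base_nat = 1.5
        np.testing.assert_allclose(scale_asfr(rates, base_nat, state), rates.asfr)
        np.testing.assert_allclose(
            scale_asfr(rates, 2 * base_nat, state), 2 * rates.asfr
        )

    def test_weighted_national_tfr_hits_target(self):
        state, rates = self._world([1.0, 1.5, 2.0], [10.0, 50.0, 500.0])
        target = 1.31
        scaled = scale_asfr(rates, target, state)
        weights = state.counts[:, 1, 15:50].sum(axis=1)
        achieved = (scaled.sum(axis=1) * weights).sum() / weights.sum()
        assert achieved == pytest.approx(target, abs=1e-12)

    def test_zero_baseline_rejected(self):
        state, rates = self._world([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValidationError):
            scale_asfr(rates, 1.5, state)


class TestLifeTable:
    def test_all_deaths_at_birth(self):
        q = np.zeros(N_AGES)
        q[0] = 1.0
        assert life_expectancy(q) == pytest.approx(0.5)

    def test_survivorship_bound(self):
        q = np.zeros(N_AGES)
        q[100] = 0.5
        assert life_expectancy(q) >= 100.0

    def test_constant_hazard_matches_geometric_oracle(self):
        # independent evaluation: l_x = 0.8^x, L_x = l_x(1 - q/2),
        # open interval L = l_100 (1 - q/2)/q
        q = np.full(N_AGES, 0.2)
        expected = sum(0.8**x * 0.9 for x in range(100)) + 0.8**100 * 0.9 / 0.2
        assert life_expectancy(q) == pytest.approx(expected, rel=1e-12)

    def test_invalid_probabilities_rejected(self):
        q = np.full(N_AGES, 0.1)
        q[3] = 1.5
        with pytest.raises(ValidationError):
            life_expectancy(q)


class TestLeTarget:
    def test_ratio_one_adds_one_year_per_decade(self):
        assert le_target(2060, 75.0, 75.0) == pytest.approx(80.0)

    def test_baseline_year_is_fixed_point(self):
        assert le_target(2010, 71.3, 74.9) == pytest.approx(71.3)

    def test_ratio_weights_growth(self):
        assert le_target(2110, 72.0, 80.0) == pytest.approx(72.0 + 9.0)


class TestMortalityInversion:
    def _schedule(self):
        ages = np.arange(N_AGES, dtype=float)
        return np.clip(1 - np.exp(-(1e-4 + 3e-5 * np.exp(0.09 * ages))), 0, 1)

    def test_fixed_point(self):
        q = self._schedule()
        _, k = mortality_for_target(q, life_expectancy(q))
        assert k == pytest.approx(1.0, abs=1e-6)

    def test_hits_target_within_tolerance(self):
        q = self._schedule()
        e0 = life_expectancy(q)
        q_new, k = mortality_for_target(q, e0 + 5.0)
        assert abs(life_expectancy(q_new) - (e0 + 5.0)) < 0.01
        assert k < 1.0

    def test_multiplier_monotone_in_target(self):
        q = self._schedule()
        e0 = life_expectancy(q)
        ks = [mortality_for_target(q, e0 + d)[1] for d in np.linspace(-8, 8, 9)]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_unreachable_target_raises(self):
        # e0 cannot fall below 0.5 (all deaths at age 0) under any scaling
        q = self._schedule()
        with pytest.raises(ValidationError):
            mortality_for_target(q, 0.2)


def _mini_geo():
    provinces = [Province("E", "east"), Province("W", "middle_west")]
    cities = [
        City("big_t1", "E", "T1"),
        City("capped", "E", "T1", ceiling=6e6),
        City("mid_t2", "W", "T2"),
        City("small_t3", "W", "T3"),
    ]
    return GeoHierarchy(provinces, cities)


def _mini_rates(geo, city_rate=0.01, prov_rate=0.005):
    n = geo.n_cities
    return RateSet(
        geo.city_names,
        geo.province_names,
        np.zeros((n, 35)),
        np.zeros((n, 2, N_AGES)),
        np.full((n, 2, N_AGES), city_rate),
        np.full((geo.n_provinces, 2, N_AGES), prov_rate),
    )


def _state_with_totals(geo, totals, year=2019):
    counts = np.zeros((geo.n_cities, 2, N_AGES))
    for i, t in enumerate(totals):
        counts[i] = t / (2 * N_AGES)
    return PopulationState(year, geo.city_names, counts)


class TestMigrationRateAt:
    def test_tier1_scenario1_doubles_by_2020(self):
        geo = _mini_geo()
        rates = _mini_rates(geo)
        prev = _state_with_totals(geo, [8e6, 5e6, 6e6, 7e6])
        city, prov = migration_rate_at(rates, geo, 1, 2020, prev)
        assert city[0, 0, 30] == pytest.approx(2 * 0.01)

    @pytest.mark.parametrize("mid", [1, 2, 3])
    def test_zero_from_2035_everywhere(self, mid):
        geo = _mini_geo()
        rates = _mini_rates(geo)
        prev = _state_with_totals(geo, [8e6, 5e6, 6e6, 7e6], year=2034)
        city, prov = migration_rate_at(rates, geo, mid, 2035, prev)
        assert np.all(city == 0) and np.all(prov == 0)

    def test_scenario3_keeps_2010_rate(self):
        geo = _mini_geo()
        rates = _mini_rates(geo)
        prev = _state_with_totals(geo, [8e6, 5e6, 6e6, 7e6])
        city, _ = migration_rate_at(rates, geo, 3, 2020, prev)
        assert city[0, 1, 20] == pytest.approx(0.01)

    def test_ceiling_zeroes_city(self):
        geo = _mini_geo()
        rates = _mini_rates(geo)
        prev = _state_with_totals(geo, [8e6, 6.5e6, 6e6, 7e6])  # capped >= 6e6
        city, _ = migration_rate_at(rates, geo, 1, 2018, prev)
        assert np.all(city[1] == 0)
        assert np.any(city[0] != 0)

    def test_size_policy_factors(self):
        geo = _mini_geo()
        rates = _mini_rates(geo)
        # mid_t2 at 4M (middle class), small_t3 at 2M (small class)
        prev = _state_with_totals(geo, [8e6, 5e6, 4e6, 2e6])
        city_before, _ = migration_rate_at(rates, geo, 3, 2019, prev)
        city_after, _ = migration_rate_at(rates, geo, 3, 2020, prev)
        # scenario 3, so the only factor besides interpolation is size policy
        assert city_before[2, 0, 0] == pytest.approx(0.01 * 0.5)
        assert city_before[3, 0, 0] == pytest.approx(0.01 * 0.5)
        assert city_after[2, 0, 0] == pytest.approx(0.01 * 0.25)
        assert city_after[3, 0, 0] == pytest.approx(0.01 * 0.10)

    def test_provincial_multiplier_amplifies_both_regions(self):
        geo = _mini_geo()
        rates = _mini_rates(geo)
        rates.prov_mig_rate[0] = 0.004  # east gains
        rates.prov_mig_rate[1] = -0.006  # middle-west loses
        prev = _state_with_totals(geo, [8e6, 5e6, 6e6, 7e6])
        _, prov = migration_rate_at(rates, geo, 1, 2020, prev)
        assert prov[0, 0, 0] == pytest.approx(0.006)
        assert prov[1, 0, 0] == pytest.approx(-0.009)

    def test_unknown_scenario_rejected(self):
        geo = _mini_geo()
        rates = _mini_rates(geo)
        prev = _state_with_totals(geo, [1e6] * 4)
        with pytest.raises(ValidationError):
            migration_rate_at(rates, geo, 9, 2020, prev)


class TestScenarioSpec:
    def test_table_targets_embedded(self):
        spec = sc.ScenarioSpec(3, 1)
        assert spec.tfr(2050) == pytest.approx(1.5)
        assert spec.tfr(2100) == pytest.approx(1.8)
        assert spec.label == "SSPFer3_SSPMigr1"

    def test_invalid_ids_rejected(self):
        with pytest.raises(ValidationError):
            sc.ScenarioSpec(6, 1)
        with pytest.raises(ValidationError):
            sc.ScenarioSpec(1, 0)

    def test_paths_frame_tidy(self):
        df = sc.ScenarioSpec(2, 3).paths_frame(np.arange(2010, 2101))
        assert set(df.columns) == {"year", "parameter", "unit", "value"}
        tfr = df[df.parameter == "tfr"].set_index("year")["value"]
        assert tfr[2050] == pytest.approx(1.3)
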