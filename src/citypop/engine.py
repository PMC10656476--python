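"""The annual cohort-component recursion.

Each projection step, for every city and sex:

* births: previous-year women aged 15-49 times the year's ASFR, split into
  male/female newborns by the year's sex ratio at birth (newborns carry no
  international-migration factor);
* survival and migration: each cohort loses deaths at its age-specific
  probability, gains its balanced internal net migration flow, then the
  whole result is scaled by (1 + net international migration rate);
* ageing: survivors move up one year; survivors of age 99 and of the open
  100+ interval pool into 100+ (the open interval is absorbing);
* any cohort driven negative by out-migration is clamped at zero and the
  shortfall logged.

Scenario paths supply the year's rates: ASFR rescaled to the national TFR
path, ASMR rescaled so each city tracks its life-expectancy growth target,
and migration rates from the scenario's multiplier/interpolation/policy
rules.  Mortality multipliers depend only on the baseline (not the
scenario), so they are computed once and shared across the 15-scenario grid.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scenarios as sc
from .core import (
    FEMALE,
    MALE,
    N_AGES,
    OPEN_AGE,
    GeoHierarchy,
    PopulationState,
    RateSet,
    ValidationError,
    total_population,
)
from .migration import apply_migration_balance, MigrationFlows
from .scenarios import ScenarioSpec

logger = logging.getLogger(__name__)


def births(prev: PopulationState, asfr: np.ndarray, srb: float) -> np.ndarray:
    """Newborns by (city, sex) from previous-year women and the year's ASFR."""
    total = (prev.counts[:, FEMALE, 15:50] * asfr).sum(axis=1)
    bm, bf = sc.birth_shares(srb)
    out = np.empty((prev.n_cities, 2))
    out[:, MALE] = total * bm
    out[:, FEMALE] = total * bf
    return out


def advance_cohorts(
    prev: PopulationState,
    asmr: np.ndarray,
    flows: np.ndarray,
    netgim: float,
    newborns: np.ndarray,
) -> tuple[np.ndarray, float]:
    """One year of survival, migration and ageing.

    ``flows`` are the balanced city net migration flows (persons, indexed
    by the age held in the previous year).  Returns the new counts array
    and the total clamping shortfall (persons that out-migration would have
    removed from already-empty cohorts).
    """
    if netgim <= -1:
        raise ValidationError("net international migration rate must be > -1")
    moved = (prev.counts * (1.0 - asmr) + flows) * (1.0 + netgim)
    new = np.zeros_like(prev.counts)
    new[:, :, 1:] = moved[:, :, :OPEN_AGE]
    new[:, :, OPEN_AGE] += moved[:, :, OPEN_AGE]  # 100+ is absorbing
    shortfall = float(-np.minimum(new, 0.0).sum())
    np.clip(new, 0.0, None, out=new)
    new[:, :, 0] = newborns  # births are not subject to the international factor
    return new, shortfall


@dataclass
class ProjectionResult:
    """All annual states of one scenario run plus bookkeeping.

    ``vitals`` holds one row per projected year with births, deaths, the
    net international migration balance and any clamping shortfall, so the
    annual identity  total(t+1) = total(t) + births - deaths + net_intl
    can be audited.  ``events`` logs (city, year) ceiling activations.
    """

    scenario: ScenarioSpec
    geo: GeoHierarchy
    states: list[PopulationState]
    events: list[tuple[str, int]] = field(default_factory=list)
    vitals: pd.DataFrame | None = None

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.states]

    def state(self, year: int) -> PopulationState:
        for s in self.states:
            if s.year == year:
                return s
        raise KeyError(f"year {year} not in projection ({self.years[0]}..{self.years[-1]})")

    def summaries(self) -> dict[str, pd.DataFrame]:
        """Total population per (year, unit) at city, province, national level."""
        out = {}
        for level in ("city", "province", "national"):
            rows = []
            for s in self.states:
                tot = total_population(s, level, self.geo)
                rows.append(
                    pd.DataFrame(
                        {"unit": tot.index, "year": s.year, "population": tot.to_numpy()}
                    )
                )
            out[level] = pd.concat(rows, ignore_index=True)
        return out

    def national_totals(self) -> pd.Series:
        return pd.Series(
            {s.year: s.total() for s in self.states}, name="population"
        )


def _baseline_e0(rates: RateSet, baseline: PopulationState) -> tuple[np.ndarray, np.ndarray]:
    """Per-(city, sex) baseline life expectancy and its national means.

    The national value per sex is the mean of city values weighted by the
    city's baseline population of that sex.
    """
    e0 = sc.life_expectancy(rates.asmr)  # (C, 2)
    weights = baseline.counts.sum(axis=2)  # (C, 2)
    wsum = weights.sum(axis=0)
    national = np.where(
        wsum > 0, (e0 * weights).sum(axis=0) / np.where(wsum > 0, wsum, 1.0),
        e0.mean(axis=0),
    )
    return e0, national


def precompute_mortality(
    rates: RateSet,
    baseline: PopulationState,
    years: range | list[int],
) -> dict[int, np.ndarray]:
    """Year -> ASMR arrays meeting each city's life-expectancy targets.

    Scenario-independent (the mortality rule is shared by all scenarios),
    so one cache serves the whole 5x3 grid.
    """
    e0_city, e0_nat = _baseline_e0(rates, baseline)
    cache: dict[int, np.ndarray] = {}
    for year in years:
        targets = sc.le_target(year, e0_city, e0_nat[None, :], baseline.year)
        k = sc.mortality_multipliers(rates.asmr, targets)
        cache[year] = np.minimum(1.0, k[..., None] * rates.asmr)
    return cache


def step_year(
    prev: PopulationState,
    scenario: ScenarioSpec,
    rates: RateSet,
    geo: GeoHierarchy,
    baseline: PopulationState,
    asmr_year: np.ndarray | None = None,
    events: list | None = None,
) -> tuple[PopulationState, dict]:
    """Advance the system one calendar year under a scenario.

    Builds the year's rate schedules, balances migration, computes births
    and advances cohorts.  Returns the new state and a vitals dict.
    """
    year = prev.year + 1
    asfr = sc.scale_asfr(rates, scenario.tfr(year), baseline)
    if asmr_year is None:
        asmr_year = precompute_mortality(rates, baseline, [year])[year]
    srb = scenario.srb(year)
    netgim = scenario.netgim(year)

    city_rate, prov_rate = sc.migration_rate_at(
        rates, geo, scenario.migration_id, year, prev
    )
    totals = prev.city_totals()
    with np.errstate(invalid="ignore"):
        capped = np.where(np.isnan(geo.city_ceilings), False, totals >= geo.city_ceilings)
    if events is not None:
        for i in np.flatnonzero(capped):
            events.append((geo.city_names[i], year))
            logger.info("ceiling active: %s in %d", geo.city_names[i], year)

    year_rates = RateSet(
        rates.cities, rates.provinces, asfr, asmr_year, city_rate, prov_rate
    )
    flows = apply_migration_balance(prev, year_rates, geo)
    newborns = births(prev, asfr, srb)
    counts, shortfall = advance_cohorts(
        prev, asmr_year, flows.city_net_adj, netgim, newborns
    )
    if shortfall > 0:
        logger.info("clamped %.3f persons of negative cohorts in %d", shortfall, year)
    deaths = float((prev.counts * asmr_year).sum())
    net_intl = float(((prev.counts * (1.0 - asmr_year) + flows.city_net_adj).sum()) * netgim)
    vit = {
        "year": year,
        "births": float(newborns.sum()),
        "deaths": deaths,
        "net_international": net_intl,
        "clamped_shortfall": shortfall,
    }
    return PopulationState(year, prev.cities, counts), vit


def project(
    baseline: PopulationState,
    rates: RateSet,
    geo: GeoHierarchy,
    fertility_id: int,
    migration_id: int,
    end_year: int = sc.END_YEAR,
    baseline_srb: float = sc.DEFAULT_BASELINE_SRB,
    mortality_cache: dict[int, np.ndarray] | None = None,
) -> ProjectionResult:
    """Project a multi-city system annually from the baseline year.

    Deterministic: identical inputs give bit-identical outputs.  With
    ``end_year`` equal to the baseline year the result holds only the
    baseline state.
    """
    if tuple(baseline.cities) != tuple(geo.city_names):
        raise ValidationError("baseline state not aligned to the geography")
    scenario = ScenarioSpec(fertility_id, migration_id, baseline_srb)
    years = range(baseline.year + 1, end_year + 1)
    if mortality_cache is None:
        mortality_cache = precompute_mortality(rates, baseline, years)
    states = [baseline]
    events: list[tuple[str, int]] = []
    vitals = []
    prev = baseline
    for year in years:
        prev, vit = step_year(
            prev, scenario, rates, geo, baseline,
            asmr_year=mortality_cache[year], events=events,
        )
        states.append(prev)
        vitals.append(vit)
    vdf = pd.DataFrame(vitals) if vitals else pd.DataFrame(
        columns=["year", "births", "deaths", "net_international", "clamped_shortfall"]
    )
    return ProjectionResult(scenario=scenario, geo=geo, states=states,
                            events=events, vitals=vdf)


def project_grid(
    baseline: PopulationState,
    rates: RateSet,
    geo: GeoHierarchy,
    end_year: int = sc.END_YEAR,
    baseline_srb: float = sc.DEFAULT_BASELINE_SRB,
    pairs: list[tuple[int, int]] | None = None,
) -> dict[tuple[int, int], ProjectionResult]:
    """Run the scenario grid (default all 5 fertility x 3 migration pairs),
    sharing the mortality cache across runs."""
    if pairs is None:
        pairs = list(itertools.product(range(1, 6), range(1, 4)))
    cache = precompute_mortality(rates, baseline, range(baseline.year + 1, end_year + 1))
    return {
        (f, m): project(
            baseline, rates, geo, f, m, end_year, baseline_srb, mortality_cache=cache
        )
        for f, m in pairs
    }


def project_constant_rates(
    baseline: PopulationState,
    asfr: np.ndarray,
    asmr: np.ndarray,
    srb: float,
    n_years: int,
    netgim: float = 0.0,
) -> list[PopulationState]:
    """Project with frozen rates and no migration (a pure Leslie system).

    Useful for conservation checks and for comparing against an explicitly
    constructed Leslie matrix.
    """
    states = [baseline]
    prev = baseline
    zero_flows = np.zeros_like(prev.counts)
    for _ in range(n_years):
        newborns = births(prev, asfr, srb)
        counts, _ = advance_cohorts(prev, asmr, zero_flows, netgim, newborns)
        prev = PopulationState(prev.year + 1, prev.cities, counts)
        states.append(prev)
    return states
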