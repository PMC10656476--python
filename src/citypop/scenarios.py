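"""Scenario parameter paths for the 5-fertility x 3-migration projection grid.

A scenario pair fixes every time-varying input of the annual recursion:

* the national TFR path (five fertility variants sharing an observed
  2010-2020 history, then linear to 2050 and 2100 targets),
* the sex ratio at birth path (linear to 1.07 by 2050, constant after),
* the net international migration rate path (UN-based -0.3015 per mille,
  constant through 2050, declining linearly to zero by 2100),
* mortality schedules obtained by scaling baseline death probabilities so
  each city's life expectancy follows a one-year-per-decade growth rule
  weighted by its 2010 ratio to the national level,
* internal net migration rate schedules: 2010 rates moved to scenario
  multipliers by 2020 (region-specific at province level, tier-specific at
  city level), then declining linearly to zero by 2035, with labor-mobility
  size-class reductions and hard population-ceiling zeroing on top.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    FERTILE_AGES,
    N_AGES,
    OPEN_AGE,
    SEXES,
    FEMALE,
    GeoHierarchy,
    PopulationState,
    RateSet,
    ValidationError,
)

BASE_YEAR = 2010
END_YEAR = 2100

# National TFR targets per fertility scenario (low .. extremely high).
TFR_TARGETS_2050 = {1: 0.7, 2: 1.3, 3: 1.5, 4: 1.8, 5: 1.8}
TFR_TARGETS_2100 = {1: 0.9, 2: 1.3, 3: 1.8, 4: 1.8, 5: 2.1}
# Observed national TFR history shared by all scenarios.
TFR_HISTORY = ((2010, 1.50), (2013, 1.50), (2017, 1.88), (2020, 1.30))

SRB_TARGET = 1.07
SRB_TARGET_YEAR = 2050

# Net international migration rate (fraction per year), UN 2005-2015 estimate.
NETGIM_RATE = -0.3015e-3
NETGIM_CONST_UNTIL = 2050

# Year by which internal migration declines to zero.
MIGRATION_ZERO_YEAR = 2035
MIGRATION_PIVOT_YEAR = 2020

# 2020 multipliers on the absolute 2010 net migration rate.
# Provinces by region: scenario 1 amplifies both gains (east) and losses
# (middle-west) by 50%, scenario 2 by 25%, scenario 3 keeps 2010 levels.
PROV_MULTIPLIERS = {
    1: {"east": 1.50, "middle_west": 1.50},
    2: {"east": 1.25, "middle_west": 1.25},
    3: {"east": 1.00, "middle_west": 1.00},
}
# Cities by tier. "Decrease" for Tier-3 shrinks the rate toward zero.
CITY_MULTIPLIERS = {
    1: {"T1": 2.00, "NT1": 1.75, "T2": 1.50, "T3": 0.25},
    2: {"T1": 1.50, "NT1": 1.25, "T2": 1.00, "T3": 0.75},
    3: {"T1": 1.00, "NT1": 1.00, "T2": 1.00, "T3": 1.00},
}

# Labor-mobility (hukou settlement) reform: migration-scale factors by city
# size class.  Small cities (< 3M residents) lose 50% of migration scale
# before 2020 and 90% from 2020 on; middle cities (3-5M) lose 50% then 75%.
SMALL_CITY_LIMIT = 3_000_000
MIDDLE_CITY_LIMIT = 5_000_000
SIZE_POLICY_FACTORS = {
    "small": {"before_2020": 0.50, "from_2020": 0.10},
    "middle": {"before_2020": 0.50, "from_2020": 0.25},
}

#: Beijing's population ceiling policy target (permanent residents).
BEIJING_POPULATION_CEILING = 23_000_000

#: Default sex ratio at birth at the 2010 baseline (male births per female
#: birth); a config knob of the synthetic world, not a published constant.
DEFAULT_BASELINE_SRB = 1.18


# ---------------------------------------------------------------------------
# fertility
# ---------------------------------------------------------------------------

def tfr_path(fertility_id: int, years) -> np.ndarray:
    """National TFR for each requested year under one fertility scenario.

    Piecewise linear through the observed anchors 2010-2020, then linear to
    the scenario's 2050 target and on to its 2100 target; constant after
    2100.  Scalar input returns a scalar.
    """
    if fertility_id not in TFR_TARGETS_2050:
        raise ValidationError(f"unknown fertility scenario {fertility_id!r}")
    anchors = list(TFR_HISTORY) + [
        (2050, TFR_TARGETS_2050[fertility_id]),
        (2100, TFR_TARGETS_2100[fertility_id]),
    ]
    xs = np.array([a[0] for a in anchors], dtype=float)
    ys = np.array([a[1] for a in anchors], dtype=float)
    yr = np.asarray(years, dtype=float)
    out = np.interp(np.clip(yr, xs[0], xs[-1]), xs, ys)
    return out if out.ndim else float(out)


def scale_asfr(
    base: RateSet, target_tfr: float, baseline: PopulationState
) -> np.ndarray:
    """Scale every city's ASFR by one national factor hitting ``target_tfr``.

    The baseline national TFR is the mean of city TFRs weighted by each
    city's baseline female population aged 15-49; a single multiplicative
    factor preserves between-city fertility differences and schedule shapes.
    """
    weights = baseline.counts[:, FEMALE, 15:50].sum(axis=1)
    tfrs = base.city_tfr()
    wsum = weights.sum()
    national = float((tfrs * weights).sum() / wsum) if wsum > 0 else float(tfrs.mean())
    if not national > 0:
        raise ValidationError("baseline national TFR must be > 0")
    return base.asfr * (target_tfr / national)


# ---------------------------------------------------------------------------
# sex ratio at birth
# ---------------------------------------------------------------------------

def srb_path(year, baseline_srb: float = DEFAULT_BASELINE_SRB):
    """Sex ratio at birth: linear from the 2010 baseline to 1.07 at 2050."""
    if not baseline_srb > 0:
        raise ValidationError("baseline_srb must be > 0")
    yr = np.asarray(year, dtype=float)
    if np.any(yr < BASE_YEAR):
        raise ValidationError("srb_path defined from 2010 on")
    frac = np.clip((yr - BASE_YEAR) / (SRB_TARGET_YEAR - BASE_YEAR), 0.0, 1.0)
    out = baseline_srb + (SRB_TARGET - baseline_srb) * frac
    return out if out.ndim else float(out)


def birth_shares(srb: float) -> tuple[float, float]:
    """Male and female shares of births for a given sex ratio at birth."""
    if not srb > 0:
        raise ValidationError("srb must be > 0")
    return srb / (1.0 + srb), 1.0 / (1.0 + srb)


# ---------------------------------------------------------------------------
# international migration
# ---------------------------------------------------------------------------

def netgim_path(year):
    """Net international migration rate (fraction/year) for a year in 2010-2100.

    Constant at -0.3015e-3 through 2050, then linear to exactly 0 at 2100.
    """
    yr = np.asarray(year, dtype=float)
    if np.any((yr < BASE_YEAR) | (yr > END_YEAR)):
        raise ValidationError("netgim_path defined for 2010..2100 only")
    decline = np.clip((END_YEAR - yr) / (END_YEAR - NETGIM_CONST_UNTIL), 0.0, 1.0)
    out = NETGIM_RATE * decline
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# mortality / life table
# ---------------------------------------------------------------------------

def life_expectancy(asmr: np.ndarray) -> float | np.ndarray:
    """Life expectancy at birth from single-year death probabilities.

    Standard period life table with a_x = 0.5 for closed ages 0..99 and an
    open 100+ interval whose person-years are l_100 / m_100+, m derived from
    the open-interval death probability.  Accepts any leading batch shape;
    the last axis must be the 101 age categories.
    """
    q = np.asarray(asmr, dtype=float)
    if q.shape[-1] != N_AGES:
        raise ValidationError(f"expected {N_AGES} age categories, got {q.shape[-1]}")
    if np.any((q < 0) | (q > 1)) or not np.all(np.isfinite(q)):
        raise ValidationError("death probabilities must lie in [0, 1]")
    p = 1.0 - q[..., :OPEN_AGE]
    # l_x for x = 0..100, with l_0 = 1
    l = np.concatenate(
        [np.ones(q.shape[:-1] + (1,)), np.cumprod(p, axis=-1)], axis=-1
    )
    # closed ages: L_x = l_x (1 - q_x / 2)
    L_closed = l[..., :OPEN_AGE] * (1.0 - 0.5 * q[..., :OPEN_AGE])
    l_open, q_open = l[..., OPEN_AGE], q[..., OPEN_AGE]
    with np.errstate(divide="ignore", invalid="ignore"):
        L_open = np.where(
            q_open > 0,
            l_open * (1.0 - 0.5 * q_open) / np.where(q_open > 0, q_open, 1.0),
            np.where(l_open > 0, np.inf, 0.0),
        )
    e0 = L_closed.sum(axis=-1) + L_open
    return float(e0) if e0.ndim == 0 else e0


def le_target(
    year: int, baseline_city_e0: float, baseline_national_e0: float,
    baseline_year: int = BASE_YEAR,
):
    """Target life expectancy for a city under the one-year-per-decade rule.

    The nominal gain of 1 year per decade is weighted by the city's initial
    ratio to the national level, so cities starting below the national LE
    gain slightly less than a full year per decade (and vice versa); the
    resulting national average growth is a little under one year per decade.
    """
    if not (np.all(np.asarray(baseline_city_e0) > 0) and np.all(np.asarray(baseline_national_e0) > 0)):
        raise ValidationError("baseline life expectancies must be > 0")
    ratio = np.asarray(baseline_city_e0) / baseline_national_e0
    out = baseline_city_e0 + (year - baseline_year) / 10.0 * ratio
    return float(out) if np.ndim(out) == 0 else out


def mortality_for_target(
    asmr: np.ndarray, target_e0: float, tol: float = 0.01
) -> tuple[np.ndarray, float]:
    """Uniformly scale a mortality schedule so life expectancy hits a target.

    Solves for the scalar k in q' = min(1, k q) such that
    life_expectancy(q') is within ``tol`` years of ``target_e0``.  Returns
    (scaled schedule, k).  k < 1 raises life expectancy.
    """
    q = np.asarray(asmr, dtype=float)

    def f(k):
        return life_expectancy(np.minimum(1.0, k * q)) - target_e0

    lo, hi = 1e-6, 1.0
    # expand upward until mortality is high enough to bracket low targets
    while f(hi) > 0 and hi < 1e6:
        hi *= 4.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValidationError(
            f"cannot bracket target e0={target_e0:.2f}: "
            f"achievable range [{life_expectancy(np.minimum(1.0, hi * q)):.2f}, "
            f"{life_expectancy(np.minimum(1.0, lo * q)):.2f}]"
        )
    k = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    # brentq converges in k; verify the e0 tolerance explicitly
    q_new = np.minimum(1.0, k * q)
    if abs(life_expectancy(q_new) - target_e0) > tol:
        raise ValidationError(f"mortality inversion missed target by > {tol} y")
    return q_new, float(k)


def mortality_multipliers(
    asmr: np.ndarray, targets: np.ndarray, n_iter: int = 64
) -> np.ndarray:
    """Vectorised bisection for per-schedule mortality multipliers.

    ``asmr`` has shape (..., 101) and ``targets`` the matching batch shape;
    returns k with that batch shape such that life_expectancy(min(1, k q))
    equals the target to well under 0.01 years.  Used by the engine, which
    needs thousands of inversions per projection.
    """
    q = np.asarray(asmr, dtype=float)
    t = np.asarray(targets, dtype=float)
    lo = np.full(t.shape, 1e-8)
    hi = np.full(t.shape, 1.0)
    # ensure upper bracket gives e0 below target where needed
    for _ in range(12):
        e_hi = life_expectancy(np.minimum(1.0, hi[..., None] * q))
        need = e_hi > t
        if not np.any(need):
            break
        hi = np.where(need, hi * 4.0, hi)
    e_lo = life_expectancy(np.minimum(1.0, lo[..., None] * q))
    if np.any(e_lo < t):
        raise ValidationError("target life expectancy not achievable from above")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        e_mid = life_expectancy(np.minimum(1.0, mid[..., None] * q))
        too_low_mortality = e_mid > t  # e0 above target -> raise mortality
        lo = np.where(too_low_mortality, mid, lo)
        hi = np.where(too_low_mortality, hi, mid)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# internal migration
# ---------------------------------------------------------------------------

def _temporal_factor(year: int, multiplier: np.ndarray) -> np.ndarray:
    """Per-unit factor on the 2010 rate for one year.

    Linear from 1 at 2010 to the scenario multiplier at 2020, then linear
    from the multiplier to 0 at 2035, and 0 afterwards.
    """
    if year <= MIGRATION_PIVOT_YEAR:
        frac = (year - BASE_YEAR) / (MIGRATION_PIVOT_YEAR - BASE_YEAR)
        return 1.0 + frac * (multiplier - 1.0)
    if year < MIGRATION_ZERO_YEAR:
        return multiplier * (MIGRATION_ZERO_YEAR - year) / (
            MIGRATION_ZERO_YEAR - MIGRATION_PIVOT_YEAR
        )
    return np.zeros_like(multiplier)


def migration_rate_at(
    base: RateSet,
    geo: GeoHierarchy,
    migration_id: int,
    year: int,
    prev: PopulationState,
    city_multipliers: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Internal net migration rate schedules for one projection year.

    Applies, in order: the scenario's 2020 tier/region multiplier on the
    2010 rate, the temporal interpolation (to the multiplier by 2020, to
    zero by 2035), the labor-mobility size-class factor (keyed on the
    previous year's city total), and the population-ceiling override, which
    zeroes a city's rate outright for any year it starts at or above its cap.
    """
    if migration_id not in PROV_MULTIPLIERS:
        raise ValidationError(f"unknown migration scenario {migration_id!r}")
    if year < BASE_YEAR:
        raise ValidationError("migration rates defined from 2010 on")
    city_mult_table = (
        CITY_MULTIPLIERS[migration_id] if city_multipliers is None else city_multipliers
    )
    prov_mult = np.array(
        [PROV_MULTIPLIERS[migration_id][r] for r in geo.province_regions]
    )
    city_mult = np.array([city_mult_table[t] for t in geo.city_tiers])

    prov_rate = base.prov_mig_rate * _temporal_factor(year, prov_mult)[:, None, None]
    city_rate = base.city_mig_rate * _temporal_factor(year, city_mult)[:, None, None]

    totals = prev.city_totals()
    key = "before_2020" if year < MIGRATION_PIVOT_YEAR else "from_2020"
    size_factor = np.ones(geo.n_cities)
    size_factor[totals < SMALL_CITY_LIMIT] = SIZE_POLICY_FACTORS["small"][key]
    size_factor[(totals >= SMALL_CITY_LIMIT) & (totals < MIDDLE_CITY_LIMIT)] = (
        SIZE_POLICY_FACTORS["middle"][key]
    )
    # ceiling: reaching the cap zeroes migration for the year, regardless
    with np.errstate(invalid="ignore"):
        capped = np.where(np.isnan(geo.city_ceilings), False, totals >= geo.city_ceilings)
    size_factor[capped] = 0.0
    city_rate = city_rate * size_factor[:, None, None]
    return city_rate, prov_rate


# ---------------------------------------------------------------------------
# the scenario bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One (fertility, migration) scenario with all derived parameter paths."""

    fertility_id: int
    migration_id: int
    baseline_srb: float = DEFAULT_BASELINE_SRB
    mig_zero_year: int = MIGRATION_ZERO_YEAR

    def __post_init__(self):
        if self.fertility_id not in TFR_TARGETS_2050:
            raise ValidationError(f"fertility_id must be 1..5, got {self.fertility_id}")
        if self.migration_id not in PROV_MULTIPLIERS:
            raise ValidationError(f"migration_id must be 1..3, got {self.migration_id}")

    @property
    def label(self) -> str:
        return f"SSPFer{self.fertility_id}_SSPMigr{self.migration_id}"

    def tfr(self, year):
        return tfr_path(self.fertility_id, year)

    def srb(self, year):
        return srb_path(year, self.baseline_srb)

    def netgim(self, year):
        return netgim_path(min(year, END_YEAR))

    @property
    def prov_multiplier_2020(self) -> dict:
        return dict(PROV_MULTIPLIERS[self.migration_id])

    @property
    def city_multiplier_2020(self) -> dict:
        return dict(CITY_MULTIPLIERS[self.migration_id])

    @property
    def size_policy(self) -> dict:
        return {k: dict(v) for k, v in SIZE_POLICY_FACTORS.items()}

    def paths_frame(self, years=None) -> pd.DataFrame:
        """Tidy (year, parameter, unit, value) export of the annual paths."""
        if years is None:
            years = np.arange(BASE_YEAR, END_YEAR + 1)
        years = np.asarray(years)
        rows = []
        for name, unit, vals in (
            ("tfr", "births/woman", self.tfr(years)),
            ("srb", "male births per female birth", self.srb(years)),
            ("netgim", "fraction/year", netgim_path(np.minimum(years, END_YEAR))),
        ):
            rows.append(
                pd.DataFrame(
                    {"year": years, "parameter": name, "unit": unit, "value": vals}
                )
            )
        return pd.concat(rows, ignore_index=True)
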