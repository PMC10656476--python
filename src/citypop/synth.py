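"""Seeded synthetic baselines with the statistical structure the model assumes.

The generator stands in for a census baseline: a geographic hierarchy with
east/middle-west provinces and tiered cities, heavy-tailed city sizes, a
stable-population age pyramid (Lotka) implied by the generated mortality and
fertility, unimodal ASFR schedules summing to each city's TFR, Gompertz-
Makeham mortality calibrated per city and sex to a life-expectancy target,
and net migration rates that are positive in the east, negative in the
middle-west, peak at young-adult ages, and sum (person-weighted) to about
zero nationally.

Randomness flows from a single seed through named substreams, so output is
bit-identical across runs and independent of generation order.  A pseudo-
census (the projection run forward and perturbed city-by-city) provides a
"truth" surface for exercising the validation metrics.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from . import scenarios as sc
from .core import (
    FEMALE,
    MALE,
    FERTILE_AGES,
    N_AGES,
    OPEN_AGE,
    City,
    GeoHierarchy,
    PopulationState,
    Province,
    RateSet,
    ValidationError,
)

TIER_ORDER = ("T1", "NT1", "T2", "T3")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic world.

    Defaults describe a mid-sized system: 5 provinces x 4 cities holding
    50 million people, TFR 1.5 (the 2010 national level), life expectancy
    72.4/77.4 years (male/female, 2010-era levels), and a baseline sex
    ratio at birth of 1.18 declining along the scenario path.
    """

    n_provinces: int = 5
    cities_per_province: int = 4
    tier_mix: tuple[float, float, float, float] = (0.10, 0.15, 0.25, 0.50)
    east_fraction: float = 0.4
    total_population: float = 50_000_000.0
    baseline_tfr: float = 1.5
    baseline_e0: tuple[float, float] = (72.4, 77.4)  # (male, female) years
    mig_rate_scale: float = 1.0
    baseline_srb: float = sc.DEFAULT_BASELINE_SRB
    seed: int = 0

    def __post_init__(self):
        if self.n_provinces < 1 or self.cities_per_province < 1:
            raise ValidationError("province and city counts must be >= 1")
        mix = np.asarray(self.tier_mix, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValidationError("tier_mix must be 4 proportions summing to 1")
        if not 0.0 <= self.east_fraction <= 1.0:
            raise ValidationError("east_fraction must lie in [0, 1]")
        if not self.total_population > 0:
            raise ValidationError("total_population must be > 0")
        if not self.baseline_tfr >= 0:
            raise ValidationError("baseline_tfr must be >= 0")


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    """Named substream of the config's seed (order-independent)."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def make_geo(config: SynthConfig) -> GeoHierarchy:
    """Generate the synthetic city register.

    East provinces come first (round(east_fraction x n) of them, at least
    one of each region when n >= 2); tiers are drawn per ``tier_mix``;
    Tier-1 cities carry a population ceiling of three times the mean city
    size, mimicking megacity caps.
    """
    rng = _rng(config, "geo")
    n_p, n_c = config.n_provinces, config.cities_per_province
    n_east = int(round(config.east_fraction * n_p))
    if n_p >= 2:
        n_east = min(max(n_east, 1), n_p - 1)
    provinces = [
        Province(f"P{p + 1:02d}", "east" if p < n_east else "middle_west")
        for p in range(n_p)
    ]
    tiers = rng.choice(TIER_ORDER, size=n_p * n_c, p=np.asarray(config.tier_mix))
    mean_city_pop = config.total_population / (n_p * n_c)
    cities = []
    for p in range(n_p):
        for c in range(n_c):
            tier = str(tiers[p * n_c + c])
            ceiling = 3.0 * mean_city_pop if tier == "T1" else None
            cities.append(
                City(f"P{p + 1:02d}C{c + 1:02d}", provinces[p].name, tier, ceiling)
            )
    return GeoHierarchy(provinces, cities)


# ---------------------------------------------------------------------------
# mortality: Gompertz-Makeham hazard calibrated to a life-expectancy target
# ---------------------------------------------------------------------------

_GOMPERTZ_SLOPE = 0.095
_MAKEHAM_BACKGROUND = 1.5e-4
_INFANT_EXTRA = 3.0e-3  # added hazard at age 0


def _q_from_level(level: float) -> np.ndarray:
    """Death probabilities q_x for a Gompertz-Makeham hazard at ``level``."""
    ages = np.arange(N_AGES, dtype=float)
    hazard = _MAKEHAM_BACKGROUND + level * np.exp(_GOMPERTZ_SLOPE * ages)
    hazard[0] += _INFANT_EXTRA
    return np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)


def _calibrate_asmr(target_e0: float) -> np.ndarray:
    """Solve the Gompertz level so life expectancy equals the target."""
    def f(log_level):
        return sc.life_expectancy(_q_from_level(np.exp(log_level))) - target_e0

    log_level = brentq(f, np.log(1e-8), np.log(1e-2), xtol=1e-10)
    return _q_from_level(np.exp(log_level))


# ---------------------------------------------------------------------------
# fertility: unimodal gamma-shaped ASFR over ages 15-49
# ---------------------------------------------------------------------------

def _asfr_shape(peak_age: float) -> np.ndarray:
    """Unit-sum unimodal fertility schedule peaking near ``peak_age``."""
    shape = 4.2
    scale = (peak_age - 14.0) / (shape - 1.0)
    w = gamma_dist.pdf(FERTILE_AGES - 14.0 + 0.5, shape, scale=scale)
    return w / w.sum()


#: Fertility level used only for the baseline age structure: the pyramid a
#: census observes reflects decades of *past* fertility near replacement,
#: not the current sub-replacement level, so the stable distribution is
#: anchored at replacement to avoid an artificially old starting population.
_PYRAMID_TFR = 2.1


def _stable_pyramid(
    asmr: np.ndarray, asfr_f: np.ndarray, bf: float
) -> np.ndarray:
    """Stable-age distribution (both sexes) for the given schedules.

    Solves Lotka's equation for the intrinsic growth rate r from the female
    net maternity function, then weights survivorship person-years by
    exp(-r(a + 1/2)).  ``asfr_f`` is a unit-sum schedule shape scaled to
    the historical pyramid fertility level.  Returns unit-sum weights of
    shape (2, 101).
    """
    # person-years lived in each age interval, per sex
    q = asmr
    p = 1.0 - q[:, :OPEN_AGE]
    l = np.concatenate([np.ones((2, 1)), np.cumprod(p, axis=1)], axis=1)
    L = np.empty((2, N_AGES))
    L[:, :OPEN_AGE] = l[:, :OPEN_AGE] * (1.0 - 0.5 * q[:, :OPEN_AGE])
    q_open = np.maximum(q[:, OPEN_AGE], 1e-12)
    L[:, OPEN_AGE] = l[:, OPEN_AGE] * (1.0 - 0.5 * q_open) / q_open

    mat = L[FEMALE, 15:50] * asfr_f * _PYRAMID_TFR * bf  # net maternity by age

    def lotka(r):
        return (np.exp(-r * (FERTILE_AGES + 0.5)) * mat).sum() - 1.0

    r = brentq(lotka, -0.1, 0.1, xtol=1e-12)
    ages = np.arange(N_AGES, dtype=float)
    w = np.exp(-r * (ages + 0.5)) * L
    return w / w.sum()


# ---------------------------------------------------------------------------
# the baseline
# ---------------------------------------------------------------------------

def make_baseline(
    config: SynthConfig, geo: GeoHierarchy
) -> tuple[PopulationState, RateSet]:
    """Generate the baseline population state and rate schedules.

    City sizes are lognormal around the mean city size; each city/sex
    mortality schedule is calibrated so its life expectancy sits within
    ±0.3 years of the configured target; city TFRs sit within ±0.8% of the
    configured TFR; migration rates follow a young-adult age profile with
    east-positive / middle-west-negative provincial levels rescaled so the
    national person-weighted net flow is zero at baseline.
    """
    if geo.n_cities != config.n_provinces * config.cities_per_province:
        raise ValidationError("geography does not match the config's city grid")
    n_c, n_p = geo.n_cities, geo.n_provinces

    # mortality, per city and sex
    rng_m = _rng(config, "mortality")
    e0_jitter = rng_m.uniform(-0.3, 0.3, size=(n_c, 2))
    asmr = np.empty((n_c, 2, N_AGES))
    for i in range(n_c):
        for s in range(2):
            asmr[i, s] = _calibrate_asmr(config.baseline_e0[s] + e0_jitter[i, s])

    # fertility, per city
    rng_f = _rng(config, "fertility")
    peaks = rng_f.uniform(25.0, 29.0, size=n_c)
    tfr_jitter = rng_f.uniform(-0.008, 0.008, size=n_c)
    asfr = np.stack(
        [
            _asfr_shape(peaks[i]) * config.baseline_tfr * (1.0 + tfr_jitter[i])
            for i in range(n_c)
        ]
    )

    # pyramid: stable distribution per city plus cellwise noise
    rng_p = _rng(config, "pyramid")
    sizes = rng_p.lognormal(mean=0.0, sigma=0.6, size=n_c)
    sizes *= config.total_population / sizes.sum()
    bm, bf = sc.birth_shares(config.baseline_srb)
    counts = np.empty((n_c, 2, N_AGES))
    for i in range(n_c):
        w = _stable_pyramid(asmr[i], asfr[i] / asfr[i].sum(), bf)
        sex_w = np.array([[bm], [bf]]) * w / (np.array([[bm], [bf]]) * w).sum()
        noise = np.exp(rng_p.normal(0.0, 0.02, size=(2, N_AGES)))
        cell = sex_w * noise
        counts[i] = sizes[i] * cell / cell.sum()

    # migration: provincial scalars balanced nationally, city variation
    rng_g = _rng(config, "migration")
    ages = np.arange(N_AGES, dtype=float)
    profile = np.exp(-0.5 * ((ages - 25.0) / 8.0) ** 2)
    east = np.array([r == "east" for r in geo.province_regions])
    if not east.any() or east.all():
        prov_scalar = np.zeros(n_p)  # one-region worlds carry no net flows
    else:
        prov_scalar = np.where(
            east,
            rng_g.uniform(0.004, 0.012, size=n_p),
            -rng_g.uniform(0.004, 0.012, size=n_p),
        ) * config.mig_rate_scale
        # rescale the gain side so the person-weighted national net flow
        # (with the age profile applied) is zero at baseline
        prov_exposed = np.zeros(n_p)
        np.add.at(
            prov_exposed, geo.city_province_idx,
            (counts * profile[None, None, :]).sum(axis=(1, 2)),
        )
        exposure = prov_exposed * prov_scalar
        gain, loss = exposure[east].sum(), -exposure[~east].sum()
        if gain > 0:
            prov_scalar[east] *= loss / gain
    city_scalar = prov_scalar[geo.city_province_idx] * (
        1.0 + rng_g.normal(0.0, 0.3, size=n_c)
    )
    sex_broadcast = np.ones((1, 2, 1))
    prov_mig = prov_scalar[:, None, None] * profile[None, None, :] * sex_broadcast
    city_mig = city_scalar[:, None, None] * profile[None, None, :] * sex_broadcast

    state = PopulationState(sc.BASE_YEAR, geo.city_names, counts)
    rates = RateSet(geo.city_names, geo.province_names, asfr, asmr, city_mig, prov_mig)
    return state, rates


def make_pseudo_census(
    baseline: PopulationState,
    rates: RateSet,
    geo: GeoHierarchy,
    scenario: sc.ScenarioSpec,
    truth_year: int,
    perturb_sd: float,
    seed: int,
) -> PopulationState:
    """A perturbed "observed" census for exercising the validation metrics.

    Projects the baseline to ``truth_year`` under the scenario, then scales
    each city's counts by an independent lognormal factor with the given
    log-scale sd.  ``perturb_sd = 0`` returns the projection itself.
    """
    from .engine import project  # local import: engine depends on this module's peers

    if truth_year <= baseline.year:
        raise ValidationError("truth_year must follow the baseline year")
    if perturb_sd < 0:
        raise ValidationError("perturb_sd must be >= 0")
    result = project(
        baseline, rates, geo, scenario.fertility_id, scenario.migration_id,
        end_year=truth_year, baseline_srb=scenario.baseline_srb,
    )
    truth = result.state(truth_year).copy()
    if perturb_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        factors = np.exp(rng.normal(0.0, perturb_sd, size=truth.n_cities))
        truth.counts *= factors[:, None, None]
    return truth
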