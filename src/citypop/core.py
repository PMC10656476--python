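"""Core domain types for the projection system.

Holds the geographic hierarchy (city -> province -> region), the population
state (counts by city, sex and single year of age with an open ``100+``
interval), and the demographic rate schedules (age-specific fertility,
age- and sex-specific mortality, net migration rates at city and province
level).  All counts are kept as real numbers throughout a projection —
rounding every year would accumulate bias over a 90-step recursion.

Serialization is plain long-format CSV so every artefact is diffable and
round-trips losslessly.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Number of single-year age categories: 0..99 plus the open interval "100+".
N_AGES = 101
#: Index of the open age interval.
OPEN_AGE = 100
SEXES = ("M", "F")
MALE, FEMALE = 0, 1
REGIONS = ("east", "middle_west")
TIERS = ("T1", "NT1", "T2", "T3")
#: Reproductive ages carried by the fertility schedule.
FERTILE_AGES = np.arange(15, 50)
AGE_LABELS = tuple(str(a) for a in range(OPEN_AGE)) + ("100+",)


class ValidationError(ValueError):
    """An input table or domain object violates a structural constraint."""


def age_label(age: int) -> str:
    return AGE_LABELS[age]


def parse_age(label: str) -> int:
    """Map an age label ("0".."99" or "100+") to its integer index."""
    s = str(label).strip()
    if s == "100+":
        return OPEN_AGE
    a = int(s)
    if not 0 <= a < OPEN_AGE:
        raise ValidationError(f"age label out of range: {label!r}")
    return a


@dataclass(frozen=True)
class Province:
    name: str
    region: str  # "east" | "middle_west"


@dataclass(frozen=True)
class City:
    name: str
    province: str
    tier: str  # "T1" | "NT1" | "T2" | "T3"
    ceiling: float | None = None  # population cap in persons, if capped


class GeoHierarchy:
    """Validated city register: cities nested in provinces with region/tier labels.

    Provides stable orderings (``city_names``, ``province_names``) that every
    array-valued object in the package is aligned to, plus vectorised lookups
    used by the migration and engine modules.
    """

    def __init__(self, provinces: list[Province], cities: list[City]):
        prov_names = [p.name for p in provinces]
        if len(set(prov_names)) != len(prov_names):
            raise ValidationError("duplicate province ids in register")
        city_names = [c.name for c in cities]
        if len(set(city_names)) != len(city_names):
            raise ValidationError("duplicate city ids in register")
        prov_set = set(prov_names)
        for p in provinces:
            if p.region not in REGIONS:
                raise ValidationError(f"unknown region label {p.region!r} for {p.name!r}")
        for c in cities:
            if c.province not in prov_set:
                raise ValidationError(f"city {c.name!r} names missing province {c.province!r}")
            if c.tier not in TIERS:
                raise ValidationError(f"unknown tier label {c.tier!r} for {c.name!r}")
            if c.ceiling is not None and not c.ceiling > 0:
                raise ValidationError(f"ceiling for {c.name!r} must be > 0")
        covered = {c.province for c in cities}
        empty = prov_set - covered
        if empty:
            raise ValidationError(f"provinces with no city: {sorted(empty)}")

        self.provinces = tuple(provinces)
        self.cities = tuple(cities)
        self.province_names = tuple(prov_names)
        self.city_names = tuple(city_names)
        self._prov_index = {n: i for i, n in enumerate(prov_names)}
        self._city_index = {n: i for i, n in enumerate(city_names)}
        #: province index of each city, aligned to city_names
        self.city_province_idx = np.array(
            [self._prov_index[c.province] for c in cities], dtype=np.intp
        )
        self.city_tiers = tuple(c.tier for c in cities)
        #: np.nan where no ceiling applies
        self.city_ceilings = np.array(
            [np.nan if c.ceiling is None else float(c.ceiling) for c in cities]
        )
        self.province_regions = tuple(p.region for p in provinces)

    @property
    def n_cities(self) -> int:
        return len(self.cities)

    @property
    def n_provinces(self) -> int:
        return len(self.provinces)

    def city_index(self, name: str) -> int:
        return self._city_index[name]

    def province_index(self, name: str) -> int:
        return self._prov_index[name]

    def cities_of_province(self, prov_idx: int) -> np.ndarray:
        return np.flatnonzero(self.city_province_idx == prov_idx)

    # -- tabular form -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        region_of = {p.name: p.region for p in self.provinces}
        return pd.DataFrame(
            {
                "city": [c.name for c in self.cities],
                "province": [c.province for c in self.cities],
                "region": [region_of[c.province] for c in self.cities],
                "tier": [c.tier for c in self.cities],
                "ceiling": [c.ceiling for c in self.cities],
            }
        )

    def save(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeoHierarchy)
            and self.provinces == other.provinces
            and self.cities == other.cities
        )


def load_geo(source: str | os.PathLike | pd.DataFrame) -> GeoHierarchy:
    """Load and validate a city register.

    The register is a table with columns ``city, province, region, tier``
    and an optional ``ceiling`` (blank = no cap).  Region is a property of
    the province; conflicting region labels for one province are rejected.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"city", "province", "region", "tier"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"register missing columns: {sorted(missing)}")
    prov_region: dict[str, str] = {}
    for _, row in df.iterrows():
        p, r = str(row["province"]), str(row["region"])
        if p in prov_region and prov_region[p] != r:
            raise ValidationError(f"province {p!r} has conflicting region labels")
        prov_region[p] = r
    provinces = [Province(p, r) for p, r in prov_region.items()]
    has_ceiling = "ceiling" in df.columns
    cities = []
    for _, row in df.iterrows():
        ceiling = None
        if has_ceiling and pd.notna(row["ceiling"]) and str(row["ceiling"]).strip() != "":
            ceiling = float(row["ceiling"])
        cities.append(City(str(row["city"]), str(row["province"]), str(row["tier"]), ceiling))
    return GeoHierarchy(provinces, cities)


@dataclass
class PopulationState:
    """Population counts for one calendar year.

    ``counts`` has shape ``(n_cities, 2, 101)`` indexed by
    (city, sex ∈ {M, F}, age ∈ {0..99, 100+}) and is non-negative real.
    """

    year: int
    cities: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (len(self.cities), len(SEXES), N_AGES)
        if self.counts.shape != expected:
            raise ValidationError(
                f"counts shape {self.counts.shape} != {expected} for {len(self.cities)} cities"
            )
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValidationError("population counts must be finite and >= 0")

    @property
    def n_cities(self) -> int:
        return len(self.cities)

    def total(self) -> float:
        return float(self.counts.sum())

    def city_totals(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def copy(self) -> "PopulationState":
        return replace(self, counts=self.counts.copy())

    def to_frame(self) -> pd.DataFrame:
        n_c = self.n_cities
        return pd.DataFrame(
            {
                "year": np.full(n_c * 2 * N_AGES, self.year),
                "city": np.repeat(list(self.cities), 2 * N_AGES),
                "sex": np.tile(np.repeat(list(SEXES), N_AGES), n_c),
                "age": np.tile(list(AGE_LABELS), n_c * 2),
                "population": self.counts.ravel(),
            }
        )

    def save(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def state_from_frame(df: pd.DataFrame) -> PopulationState:
    """Rebuild a PopulationState from its long CSV form (one year only)."""
    years = df["year"].unique()
    if len(years) != 1:
        raise ValidationError(f"expected a single year, found {sorted(years)}")
    cities = tuple(pd.unique(df["city"]))
    cidx = {c: i for i, c in enumerate(cities)}
    sidx = {s: i for i, s in enumerate(SEXES)}
    counts = np.zeros((len(cities), 2, N_AGES))
    rows_c = df["city"].map(cidx).to_numpy()
    rows_s = df["sex"].map(sidx).to_numpy()
    if np.any(pd.isna(rows_s)):
        raise ValidationError("sex labels must be 'M' or 'F'")
    rows_a = df["age"].map(parse_age).to_numpy()
    counts[rows_c, rows_s, rows_a] = df["population"].to_numpy(dtype=float)
    return PopulationState(int(years[0]), cities, counts)


def load_state(path: str | os.PathLike) -> PopulationState:
    df = pd.read_csv(path, dtype={"age": str}, float_precision="round_trip")
    return state_from_frame(df)


@dataclass
class RateSet:
    """Baseline demographic rate schedules aligned to a GeoHierarchy.

    asfr            (n_cities, 35)       births/woman/year, ages 15..49
    asmr            (n_cities, 2, 101)   annual death probability q_x in [0,1]
    city_mig_rate   (n_cities, 2, 101)   net migrants per resident per year
    prov_mig_rate   (n_provinces, 2, 101)  same, at province level

    Migration rates may be negative (net out-migration) but must stay > −1.
    """

    cities: tuple[str, ...]
    provinces: tuple[str, ...]
    asfr: np.ndarray
    asmr: np.ndarray
    city_mig_rate: np.ndarray
    prov_mig_rate: np.ndarray

    def __post_init__(self):
        self.asfr = np.asarray(self.asfr, dtype=float)
        self.asmr = np.asarray(self.asmr, dtype=float)
        self.city_mig_rate = np.asarray(self.city_mig_rate, dtype=float)
        self.prov_mig_rate = np.asarray(self.prov_mig_rate, dtype=float)
        n_c, n_p = len(self.cities), len(self.provinces)
        if self.asfr.shape != (n_c, len(FERTILE_AGES)):
            raise ValidationError(f"asfr shape {self.asfr.shape} != {(n_c, len(FERTILE_AGES))}")
        if self.asmr.shape != (n_c, 2, N_AGES):
            raise ValidationError(f"asmr shape {self.asmr.shape}")
        if self.city_mig_rate.shape != (n_c, 2, N_AGES):
            raise ValidationError(f"city_mig_rate shape {self.city_mig_rate.shape}")
        if self.prov_mig_rate.shape != (n_p, 2, N_AGES):
            raise ValidationError(f"prov_mig_rate shape {self.prov_mig_rate.shape}")
        if np.any(self.asfr < 0):
            raise ValidationError("asfr must be >= 0")
        if np.any((self.asmr < 0) | (self.asmr > 1)):
            raise ValidationError("asmr must lie in [0, 1]")
        for name, r in (("city", self.city_mig_rate), ("province", self.prov_mig_rate)):
            if np.any(r <= -1):
                raise ValidationError(f"{name} migration rates must be > -1")
        if not np.all(np.isfinite(self.city_tfr())):
            raise ValidationError("city TFR must be finite")

    def city_tfr(self) -> np.ndarray:
        """Total fertility rate per city: sum of ASFR over ages 15–49."""
        return self.asfr.sum(axis=1)

    def copy(self) -> "RateSet":
        return RateSet(
            self.cities,
            self.provinces,
            self.asfr.copy(),
            self.asmr.copy(),
            self.city_mig_rate.copy(),
            self.prov_mig_rate.copy(),
        )

    # -- tabular form -----------------------------------------------------

    def save(self, outdir: str | os.PathLike) -> None:
        outdir = os.fspath(outdir)
        n_c, n_p = len(self.cities), len(self.provinces)
        pd.DataFrame(
            {
                "city": np.repeat(list(self.cities), len(FERTILE_AGES)),
                "age": np.tile(FERTILE_AGES, n_c),
                "rate": self.asfr.ravel(),
            }
        ).to_csv(os.path.join(outdir, "asfr.csv"), index=False)

        def long3(units, arr, unit_col):
            return pd.DataFrame(
                {
                    unit_col: np.repeat(list(units), 2 * N_AGES),
                    "sex": np.tile(np.repeat(list(SEXES), N_AGES), len(units)),
                    "age": np.tile(list(AGE_LABELS), len(units) * 2),
                    "rate": arr.ravel(),
                }
            )

        long3(self.cities, self.asmr, "city").to_csv(
            os.path.join(outdir, "asmr.csv"), index=False
        )
        long3(self.cities, self.city_mig_rate, "city").to_csv(
            os.path.join(outdir, "migration_city.csv"), index=False
        )
        long3(self.provinces, self.prov_mig_rate, "province").to_csv(
            os.path.join(outdir, "migration_province.csv"), index=False
        )


def load_rates(indir: str | os.PathLike, geo: GeoHierarchy) -> RateSet:
    """Read the four rate tables written by :meth:`RateSet.save`."""
    indir = os.fspath(indir)
    cidx = {c: i for i, c in enumerate(geo.city_names)}
    pidx = {p: i for i, p in enumerate(geo.province_names)}
    sidx = {s: i for i, s in enumerate(SEXES)}

    asfr = np.zeros((geo.n_cities, len(FERTILE_AGES)))
    df = pd.read_csv(os.path.join(indir, "asfr.csv"), float_precision="round_trip")
    asfr[df["city"].map(cidx), df["age"].astype(int) - 15] = df["rate"]

    def read3(fname, units_idx, unit_col, n_units):
        arr = np.zeros((n_units, 2, N_AGES))
        d = pd.read_csv(
            os.path.join(indir, fname), dtype={"age": str},
            float_precision="round_trip",
        )
        arr[
            d[unit_col].map(units_idx),
            d["sex"].map(sidx),
            d["age"].map(parse_age),
        ] = d["rate"]
        return arr

    asmr = read3("asmr.csv", cidx, "city", geo.n_cities)
    cmr = read3("migration_city.csv", cidx, "city", geo.n_cities)
    pmr = read3("migration_province.csv", pidx, "province", geo.n_provinces)
    return RateSet(geo.city_names, geo.province_names, asfr, asmr, cmr, pmr)


def total_population(
    state: PopulationState, level: str, geo: GeoHierarchy
) -> pd.Series:
    """Aggregate a state's counts to city, province or national totals.

    Totals are additive across levels: the national total equals the sum of
    provincial totals equals the sum of city totals.
    """
    missing = set(state.cities) - set(geo.city_names)
    if missing:
        raise ValidationError(f"cities absent from geography: {sorted(missing)}")
    city_tot = pd.Series(state.city_totals(), index=list(state.cities), name="population")
    if level == "city":
        return city_tot
    prov_of = {c.name: c.province for c in geo.cities}
    prov_tot = city_tot.groupby(city_tot.index.map(prov_of)).sum()
    prov_tot = prov_tot.reindex(
        [p for p in geo.province_names if p in set(prov_tot.index)]
    ).fillna(0.0)
    prov_tot.name = "population"
    if level == "province":
        return prov_tot
    if level == "national":
        return pd.Series({"national": float(city_tot.sum())}, name="population")
    raise ValidationError(f"unknown aggregation level {level!r}")
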