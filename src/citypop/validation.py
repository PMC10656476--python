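"""Projection-accuracy metrics and error reports.

Two standard indicators compare a projected value P against an observed
value A:

    PE(%)  = (P - A) / A x 100     (signed; positive = overestimate)
    APE(%) = |P - A| / A x 100

The error report evaluates them on total population at the national,
provincial and city level, summarises the city distribution as shares of
cities below APE thresholds (both count-weighted and weighted by observed
population), and compares the national age *structure* — the proportion of
the population in each age group, not the counts — for a configurable
grouping (default: 0-14, then five-year groups to 85+).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeoHierarchy, PopulationState, ValidationError
from .engine import ProjectionResult

#: 0-14, 15-19, ..., 80-84, 85+ (the open 100+ interval folds into 85+)
DEFAULT_AGE_GROUPS: tuple[tuple[int, int], ...] = ((0, 14),) + tuple(
    (a, a + 4) for a in range(15, 85, 5)
) + ((85, 100),)

DEFAULT_APE_THRESHOLDS = (5.0, 10.0)


def pe(projected: float, actual: float) -> float:
    """Algebraic percentage error; positive when the projection overestimates."""
    if not actual > 0:
        raise ValidationError("actual value must be > 0")
    return (projected - actual) / actual * 100.0


def ape(projected: float, actual: float) -> float:
    """Absolute percentage error: |PE|."""
    return abs(pe(projected, actual))


def _group_label(lo: int, hi: int) -> str:
    return f"{lo}+" if hi >= 100 else f"{lo}-{hi}"


def _age_group_shares(counts: np.ndarray, groups) -> np.ndarray:
    """National age-group proportions (summing over cities and sexes)."""
    by_age = counts.sum(axis=(0, 1))
    total = by_age.sum()
    return np.array([by_age[lo : hi + 1].sum() / total for lo, hi in groups])


@dataclass
class ErrorReport:
    """PE/APE of a projection against an observed state at one year."""

    year: int
    national_pe: float
    national_ape: float
    province: pd.DataFrame  # unit, pe, ape
    city: pd.DataFrame  # unit, pe, ape
    shares: pd.DataFrame  # threshold, share, pop_weighted_share
    age_structure: pd.DataFrame  # group, projected_share, actual_share, pe, ape
    excluded_cities: tuple[str, ...] = ()

    @property
    def province_mean_pe(self) -> float:
        return float(self.province["pe"].mean())

    @property
    def province_mean_ape(self) -> float:
        return float(self.province["ape"].mean())

    @property
    def city_mean_pe(self) -> float:
        return float(self.city["pe"].mean())

    @property
    def city_mean_ape(self) -> float:
        return float(self.city["ape"].mean())

    def summary_frame(self) -> pd.DataFrame:
        """The national/provincial/city PE-APE block."""
        return pd.DataFrame(
            {
                "level": ["national", "provincial_mean", "city_mean"],
                "pe": [self.national_pe, self.province_mean_pe, self.city_mean_pe],
                "ape": [self.national_ape, self.province_mean_ape, self.city_mean_ape],
            }
        )

    def to_csv(self, outdir) -> None:
        import os

        outdir = os.fspath(outdir)
        self.summary_frame().to_csv(os.path.join(outdir, "errors_summary.csv"), index=False)
        self.province.to_csv(os.path.join(outdir, "errors_province.csv"), index=False)
        self.city.to_csv(os.path.join(outdir, "errors_city.csv"), index=False)
        self.shares.to_csv(os.path.join(outdir, "errors_ape_shares.csv"), index=False)
        self.age_structure.to_csv(
            os.path.join(outdir, "errors_age_structure.csv"), index=False
        )


def error_report(
    projection: ProjectionResult | PopulationState,
    truth: PopulationState,
    geo: GeoHierarchy,
    age_grouping=DEFAULT_AGE_GROUPS,
    ape_thresholds=DEFAULT_APE_THRESHOLDS,
) -> ErrorReport:
    """Full error report of a projection against an observed state.

    Cities absent from the truth (or with zero observed population) are
    excluded from every statistic and listed in ``excluded_cities``.
    """
    proj_state = (
        projection.state(truth.year)
        if isinstance(projection, ProjectionResult)
        else projection
    )
    if proj_state.year != truth.year:
        raise ValidationError(
            f"projection year {proj_state.year} != truth year {truth.year}"
        )
    common = [c for c in proj_state.cities if c in set(truth.cities)]
    if not common:
        raise ValidationError("projection and truth share no cities")
    excluded = [c for c in proj_state.cities if c not in set(truth.cities)]

    p_idx = {c: i for i, c in enumerate(proj_state.cities)}
    t_idx = {c: i for i, c in enumerate(truth.cities)}
    p_tot = proj_state.city_totals()
    t_tot = truth.city_totals()
    proj_c = np.array([p_tot[p_idx[c]] for c in common])
    act_c = np.array([t_tot[t_idx[c]] for c in common])
    zero = act_c <= 0
    if zero.any():
        dropped = [c for c, z in zip(common, zero) if z]
        warnings.warn(f"excluding cities with zero observed population: {dropped}")
        excluded += dropped
        keep = ~zero
        common = [c for c, k in zip(common, keep) if k]
        proj_c, act_c = proj_c[keep], act_c[keep]
        if not common:
            raise ValidationError("no city has positive observed population")

    pe_c = (proj_c - act_c) / act_c * 100.0
    city_df = pd.DataFrame({"unit": common, "pe": pe_c, "ape": np.abs(pe_c)})
    city_df = city_df.sort_values("unit", kind="stable").reset_index(drop=True)

    prov_of = {c.name: c.province for c in geo.cities}
    prov_proj: dict[str, float] = {}
    prov_act: dict[str, float] = {}
    for c, pv, av in zip(common, proj_c, act_c):
        p = prov_of[c]
        prov_proj[p] = prov_proj.get(p, 0.0) + pv
        prov_act[p] = prov_act.get(p, 0.0) + av
    prov_units = sorted(prov_proj)
    pe_p = np.array([pe(prov_proj[p], prov_act[p]) for p in prov_units])
    prov_df = pd.DataFrame({"unit": prov_units, "pe": pe_p, "ape": np.abs(pe_p)})

    nat_pe = pe(proj_c.sum(), act_c.sum())

    rows = []
    apes = np.abs(pe_c)
    for th in ape_thresholds:
        below = apes < th
        rows.append(
            {
                "threshold": th,
                "share": float(below.mean()),
                "pop_weighted_share": float(act_c[below].sum() / act_c.sum()),
            }
        )
    shares_df = pd.DataFrame(rows)

    # age structure: proportions at the national level over the common cities
    keep_p = np.array([p_idx[c] for c in common])
    keep_t = np.array([t_idx[c] for c in common])
    ps = _age_group_shares(proj_state.counts[keep_p], age_grouping)
    ts = _age_group_shares(truth.counts[keep_t], age_grouping)
    pe_g = (ps - ts) / ts * 100.0
    age_df = pd.DataFrame(
        {
            "group": [_group_label(lo, hi) for lo, hi in age_grouping],
            "projected_share": ps,
            "actual_share": ts,
            "pe": pe_g,
            "ape": np.abs(pe_g),
        }
    )

    return ErrorReport(
        year=truth.year,
        national_pe=nat_pe,
        national_ape=abs(nat_pe),
        province=prov_df,
        city=city_df,
        shares=shares_df,
        age_structure=age_df,
        excluded_cities=tuple(excluded),
    )
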