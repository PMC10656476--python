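"""Net internal migration flows and the two-level rebalancing constraints.

Net migration is modelled with rates, not origin-destination flows, so the
raw person-count flows they imply are generally inconsistent: provincial
nets need not sum to zero nationally, and city nets need not sum to their
province's net.  Two constraints restore consistency, separately for every
(sex, single age) cell:

1. national closure — adjusted provincial nets sum to 0: the side (gains or
   losses) with the larger total magnitude is proportionally cut back to
   match the smaller side;
2. provincial consistency — adjusted city nets within a province sum to the
   adjusted provincial net, by proportional rescaling where the signs agree
   and by population-weighted additive redistribution otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AGE_LABELS,
    N_AGES,
    SEXES,
    GeoHierarchy,
    PopulationState,
    RateSet,
    ValidationError,
)


@dataclass
class MigrationFlows:
    """Person-count net migration flows for one projection year.

    ``city_net`` / ``prov_net`` are the raw flows implied by the rates;
    ``*_adj`` are their balanced counterparts.  ``prev_counts`` keeps the
    population the flows were computed from (needed for the additive
    fallback of the city-level reconciliation and for audit export).
    """

    cities: tuple[str, ...]
    provinces: tuple[str, ...]
    city_net: np.ndarray  # (C, 2, 101)
    prov_net: np.ndarray  # (P, 2, 101)
    prev_counts: np.ndarray  # (C, 2, 101)
    city_net_adj: np.ndarray | None = None
    prov_net_adj: np.ndarray | None = None

    def to_frame(self, geo: GeoHierarchy, year: int | None = None) -> pd.DataFrame:
        """Long audit export: one row per (city, sex, age)."""
        n_c = len(self.cities)
        prov = [geo.cities[i].province for i in range(n_c)]
        adj = self.city_net_adj if self.city_net_adj is not None else np.full_like(
            self.city_net, np.nan
        )
        df = pd.DataFrame(
            {
                "province": np.repeat(prov, 2 * N_AGES),
                "city": np.repeat(list(self.cities), 2 * N_AGES),
                "sex": np.tile(np.repeat(list(SEXES), N_AGES), n_c),
                "age": np.tile(list(AGE_LABELS), n_c * 2),
                "net": self.city_net.ravel(),
                "net_adjusted": adj.ravel(),
            }
        )
        if year is not None:
            df.insert(0, "year", year)
        return df


def province_aggregate(counts: np.ndarray, geo: GeoHierarchy) -> np.ndarray:
    """Sum a (city, sex, age) array to (province, sex, age)."""
    out = np.zeros((geo.n_provinces,) + counts.shape[1:])
    np.add.at(out, geo.city_province_idx, counts)
    return out


def flows_from_rates(
    prev: PopulationState, rates: RateSet, geo: GeoHierarchy
) -> MigrationFlows:
    """Raw net flows: previous-year population times its own net rate.

    City flows are elementwise products per (city, sex, age); provincial
    flows apply the provincial rate to the province-summed population.
    """
    if prev.cities != tuple(rates.cities):
        raise ValidationError("rates not aligned to the population state's cities")
    city_net = prev.counts * rates.city_mig_rate
    prov_pop = province_aggregate(prev.counts, geo)
    prov_net = prov_pop * rates.prov_mig_rate
    return MigrationFlows(
        cities=prev.cities,
        provinces=geo.province_names,
        city_net=city_net,
        prov_net=prov_net,
        prev_counts=prev.counts,
    )


def _zero_residual(adj: np.ndarray, target: np.ndarray) -> None:
    """Absorb the float residual of a (unit, sex, age) balance in place.

    Assigns ``sum over units - target`` to the largest-magnitude unit per
    (sex, age) cell so the constraint holds exactly, not just to rounding.
    """
    residual = adj.sum(axis=0) - target
    idx = np.abs(adj).argmax(axis=0)
    s, a = np.meshgrid(
        np.arange(adj.shape[1]), np.arange(adj.shape[2]), indexing="ij"
    )
    adj[idx, s, a] -= residual


def balance_provinces(flows: MigrationFlows) -> MigrationFlows:
    """Enforce zero national net migration per (sex, age).

    For each cell, whichever side (total gains S+ or total losses S-) has
    the larger magnitude is scaled by min(S+, S-)/max(S+, S-); the smaller
    side is untouched.  Scaling factors lie in [0, 1], so no provincial
    flow changes sign or grows, and the operation is idempotent.
    """
    x = flows.prov_net
    pos = np.where(x > 0, x, 0.0)
    neg = np.where(x < 0, -x, 0.0)
    s_pos = pos.sum(axis=0)
    s_neg = neg.sum(axis=0)
    m = np.minimum(s_pos, s_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_pos = np.where(s_pos > m, np.where(s_pos > 0, m / s_pos, 1.0), 1.0)
        f_neg = np.where(s_neg > m, np.where(s_neg > 0, m / s_neg, 1.0), 1.0)
    adj = np.where(x > 0, x * f_pos, x * f_neg)
    _zero_residual(adj, np.zeros(x.shape[1:]))
    flows.prov_net_adj = adj
    return flows


def reconcile_cities(flows: MigrationFlows, geo: GeoHierarchy) -> MigrationFlows:
    """Make city nets sum to the adjusted provincial net per (sex, age).

    Within each province: where the raw city sum C is nonzero and shares the
    sign of the provincial target T, every city flow is rescaled by T/C.
    Where C = 0 or the signs disagree (including T = 0 with C != 0), the
    discrepancy T - C is distributed additively across the province's
    cities in proportion to their previous-year population of that cell.
    """
    if flows.prov_net_adj is None:
        raise ValidationError("balance_provinces must run before reconcile_cities")
    adj = flows.city_net.copy()
    for p in range(geo.n_provinces):
        cid = geo.cities_of_province(p)
        c = flows.city_net[cid]
        C = c.sum(axis=0)
        T = flows.prov_net_adj[p]
        mult = (C != 0) & (np.sign(C) == np.sign(T))
        safe_C = np.where(C != 0, C, 1.0)
        scaled = c * np.where(mult, T / safe_C, 1.0)

        need_add = ~mult
        pop = flows.prev_counts[cid]
        psum = pop.sum(axis=0)
        gap = T - C
        bad = need_add & (psum <= 0) & (np.abs(gap) > 0)
        if np.any(bad):
            raise ValidationError(
                f"province {geo.province_names[p]!r} has zero population but a "
                "nonzero migration target in some (sex, age) cell"
            )
        w = pop / np.where(psum > 0, psum, 1.0)
        added = c + gap * w
        out = np.where(mult, scaled, added)
        _zero_residual(out, T)
        adj[cid] = out
    flows.city_net_adj = adj
    return flows


def apply_migration_balance(
    prev: PopulationState, rates: RateSet, geo: GeoHierarchy
) -> MigrationFlows:
    """Flows from rates, then both balancing steps; invariants hold on output."""
    flows = flows_from_rates(prev, rates, geo)
    flows = balance_provinces(flows)
    flows = reconcile_cities(flows, geo)
    return flows
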