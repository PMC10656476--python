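"""Writers matching the published data-record layout.

One long CSV per (unit, scenario) named
``Pop_TOTAL_<unitname>_SSPFer<x>_SSPMigr<x>.csv`` (national files omit the
unit name) with columns year, sex (M/F), age (0..99, 100+) and population,
plus cross-scenario summary tables ``City_TOTAL.csv``,
``Province_TOTAL.csv``, ``Pop_TOTAL.csv`` and the ``city_name.csv``
city-to-province register.  Row order and float formatting are fixed, so
identical runs produce byte-identical files; floats are written with their
shortest round-trip representation so read-back reproduces in-memory
values exactly.
"""
from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from .core import AGE_LABELS, N_AGES, SEXES, GeoHierarchy, ValidationError
from .engine import ProjectionResult
from .migration import province_aggregate


def sanitize_name(name: str) -> str:
    """Filename-safe unit name: spaces to underscores, drop odd characters."""
    return re.sub(r"[^A-Za-z0-9_\-]", "", name.replace(" ", "_"))


def _unit_frame(years: list[int], counts_by_year: list[np.ndarray]) -> pd.DataFrame:
    """Long (year, sex, age, population) frame for one unit."""
    frames = []
    for year, counts in zip(years, counts_by_year):
        frames.append(
            pd.DataFrame(
                {
                    "year": np.full(2 * N_AGES, year),
                    "sex": np.repeat(list(SEXES), N_AGES),
                    "age": np.tile(list(AGE_LABELS), 2),
                    "population": counts.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_outputs(
    results: list[ProjectionResult] | dict,
    geo: GeoHierarchy,
    outdir: str | os.PathLike,
) -> pd.DataFrame:
    """Write the full data-record layout; returns the file manifest.

    The manifest lists every file with its row count; sanitized unit names
    are recorded alongside the originals.
    """
    if isinstance(results, dict):
        results = list(results.values())
    if not results:
        raise ValidationError("no projection results to write")
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)

    manifest_rows = []
    city_tot, prov_tot, nat_tot = [], [], []

    def emit(df: pd.DataFrame, fname: str, unit: str = "") -> None:
        df.to_csv(os.path.join(outdir, fname), index=False)
        manifest_rows.append({"file": fname, "rows": len(df), "unit": unit})

    for res in results:
        label = res.scenario.label
        years = res.years
        for i, city in enumerate(geo.city_names):
            df = _unit_frame(years, [s.counts[i] for s in res.states])
            emit(df, f"Pop_TOTAL_{sanitize_name(city)}_{label}.csv", city)
        prov_counts = [province_aggregate(s.counts, geo) for s in res.states]
        for j, prov in enumerate(geo.province_names):
            df = _unit_frame(years, [pc[j] for pc in prov_counts])
            emit(df, f"Pop_TOTAL_{sanitize_name(prov)}_{label}.csv", prov)
        nat_counts = [s.counts.sum(axis=0) for s in res.states]
        emit(_unit_frame(years, nat_counts), f"Pop_TOTAL_{label}.csv", "national")

        for s in res.states:
            totals = s.city_totals()
            for i, city in enumerate(geo.city_names):
                city_tot.append((city, s.year, label, totals[i]))
            ptot = province_aggregate(s.counts, geo).sum(axis=(1, 2))
            for j, prov in enumerate(geo.province_names):
                prov_tot.append((prov, s.year, label, ptot[j]))
            nat_tot.append(("China_synthetic", s.year, label, totals.sum()))

    cols = ["unit", "year", "scenario", "population"]
    emit(pd.DataFrame(city_tot, columns=cols), "City_TOTAL.csv")
    emit(pd.DataFrame(prov_tot, columns=cols), "Province_TOTAL.csv")
    emit(pd.DataFrame(nat_tot, columns=cols), "Pop_TOTAL.csv")

    name_df = pd.DataFrame(
        {
            "city": list(geo.city_names),
            "province": [c.province for c in geo.cities],
            "file_name": [sanitize_name(c) for c in geo.city_names],
        }
    )
    emit(name_df, "city_name.csv")

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest


def read_unit_file(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-unit output file back as written."""
    return pd.read_csv(path, dtype={"age": str}, float_precision="round_trip")
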