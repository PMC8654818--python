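"""Deterministic data preparation: from raw survey and catch tables to
model-ready datasets.

Everything here is exact bookkeeping — unit conversions, the categorical
coral-cover midpoint table, duplicate resolution at the grid-site level,
catch aggregation across fisheries, lag pairing of catch with CoTS
densities, length-weight biomass, and cross-group catch correlations.
Each data-altering decision (dropping closed-zone reefs, averaging
multiple reefs, summing duplicate fishery rows) is recorded in an
:class:`AuditLog` that can be written as JSON lines.

Conventions: reporting years run 1 July-30 June and are labelled by the
end year; CoTS density is individuals per minute (tows are 2 minutes);
fish densities are per 1000 m² (belts are 250 m²).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COVER_CATEGORY_MAP",
    "COVER_CATEGORY_ORDER",
    "AuditLog",
    "convert_cover_category",
    "convert_cover_series",
    "cots_density_per_minute",
    "site_year_cots_from_tows",
    "resolve_duplicates",
    "aggregate_catch",
    "aggregate_catch_table",
    "build_lagged_pairs",
    "fish_density_per_1000m2",
    "biomass_from_length",
    "parse_lengths",
    "site_mean_length",
    "reserve_site_table",
    "pairwise_lag_correlations",
]

#: Manta-tow coral-cover categories -> proportion (category midpoints).
COVER_CATEGORY_MAP = {
    "0": 0.0,
    "1": 0.05, "1L": 0.025, "1U": 0.075,
    "2": 0.2, "2L": 0.15, "2U": 0.25,
    "3": 0.4, "3L": 0.35, "3U": 0.45,
    "4": 0.625, "4L": 0.5625, "4U": 0.6875,
    "5": 0.875, "5L": 0.8125, "5U": 0.9375,
}

#: Categories in increasing cover order (L sub-category below the main
#: category, U above it).
COVER_CATEGORY_ORDER = tuple(
    sorted(COVER_CATEGORY_MAP, key=COVER_CATEGORY_MAP.__getitem__)
)

TOW_MINUTES = 2.0
BELT_AREA_M2 = 250.0


class AuditLog:
    """Machine-readable record of every data-prep decision."""

    def __init__(self):
        self.events: list[dict] = []

    def record(self, action: str, **details) -> None:
        self.events.append({"action": action, **details})

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e, default=str) + "\n")

    def __len__(self):
        return len(self.events)


def convert_cover_category(code: str) -> float:
    """Map one categorical coral-cover code to its midpoint proportion."""
    try:
        return COVER_CATEGORY_MAP[str(code)]
    except KeyError:
        raise KeyError(f"unknown coral-cover category code {code!r}") from None


def convert_cover_series(codes: pd.Series) -> pd.Series:
    """Vectorized midpoint conversion; unknown codes raise, naming the code."""
    out = codes.astype(str).map(COVER_CATEGORY_MAP)
    if out.isna().any():
        bad = codes[out.isna()].iloc[0]
        raise KeyError(f"unknown coral-cover category code {bad!r}")
    return out.astype(float)


def cots_density_per_minute(tow_counts) -> float:
    """Mean CoTS per minute over a set of 2-minute tows."""
    counts = np.asarray(list(tow_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("cannot compute a density from an empty tow set")
    if np.any(counts < 0):
        raise ValueError("tow counts must be non-negative")
    return float(np.mean(counts / TOW_MINUTES))


def site_year_cots_from_tows(tows: pd.DataFrame) -> pd.DataFrame:
    """Reef-level site-year table from tow records.

    One row per (grid_site, year, zoning, reef_id) with the per-minute
    CoTS density and the mean coral-cover proportion over tows — the
    input expected by :func:`resolve_duplicates`.
    """
    df = tows.copy()
    df["coral_cover"] = convert_cover_series(df["cover_code"])
    df["per_min"] = df["cots_count"].astype(float) / TOW_MINUTES
    g = df.groupby(["grid_site", "year", "zoning", "reef_id"], sort=True)
    out = g.agg(cots_density=("per_min", "mean"), coral_cover=("coral_cover", "mean"))
    return out.reset_index()


def resolve_duplicates(
    reef_table: pd.DataFrame,
    *,
    open_only: bool = False,
    audit: AuditLog | None = None,
) -> pd.DataFrame:
    """Collapse multiple reefs per grid-site-year to one record.

    Rules, applied per (grid_site, year):

    1. if reefs from both zonings are present, the closed-zone reefs are
       dropped (those reefs cannot have been fished);
    2. multiple reefs of the surviving zoning are averaged (unweighted
       arithmetic mean of density and cover);
    3. with ``open_only=True`` (the fisheries-lag stream) any site-year
       whose records come from closed zones only is removed.

    Every drop and average is written to the audit log.  The output never
    has more rows than the input.
    """
    audit = audit if audit is not None else AuditLog()
    rows = []
    for (site, year), grp in reef_table.groupby(["grid_site", "year"], sort=True):
        zonings = set(grp["zoning"])
        if {"open", "closed"} <= zonings:
            n_drop = int((grp["zoning"] == "closed").sum())
            audit.record(
                "drop_closed_zone_reefs", grid_site=site, year=int(year), n_dropped=n_drop
            )
            grp = grp[grp["zoning"] == "open"]
        zoning = grp["zoning"].iloc[0]
        if open_only and zoning == "closed":
            audit.record(
                "drop_closed_only_site_year", grid_site=site, year=int(year),
                n_dropped=len(grp),
            )
            continue
        if len(grp) > 1:
            audit.record(
                "average_reefs", grid_site=site, year=int(year),
                zoning=zoning, n_reefs=len(grp),
            )
        rows.append(
            {
                "grid_site": site,
                "year": int(year),
                "zoning": zoning,
                "cots_density": float(grp["cots_density"].mean()),
                "coral_cover": float(grp["coral_cover"].mean()),
                "n_reefs": len(grp),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["grid_site", "year", "zoning", "cots_density", "coral_cover", "n_reefs"],
    )


def aggregate_catch(
    records: pd.DataFrame,
    *,
    group: str | None = None,
    grid_site: str | None = None,
    year: int | None = None,
    audit: AuditLog | None = None,
) -> float:
    """Total retained kg across fisheries for one group/site/year slice.

    Missing fisheries contribute zero; duplicate rows for the same
    fishery are summed with a logged warning; negative masses are a
    validation error.
    """
    df = records
    for col, val in (("group", group), ("grid_site", grid_site), ("year", year)):
        if val is not None:
            df = df[df[col] == val]
    if len(df) == 0:
        return 0.0
    if (df["retained_kg"] < 0).any():
        raise ValueError("retained_kg must be non-negative")
    dup = df.groupby("fishery").size()
    if (dup > 1).any():
        which = list(dup[dup > 1].index)
        warnings.warn(
            f"duplicate fishery rows summed for fisheries {which}", UserWarning
        )
        if audit is not None:
            audit.record(
                "sum_duplicate_fishery_rows", group=group, grid_site=grid_site,
                year=year, fisheries=which,
            )
    return float(df["retained_kg"].sum())


def aggregate_catch_table(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Site-year totals (kg across the four fisheries) for one fish group."""
    if (records["retained_kg"] < 0).any():
        raise ValueError("retained_kg must be non-negative")
    sub = records[records["group"] == group]
    out = (
        sub.groupby(["grid_site", "year"], sort=True)["retained_kg"]
        .sum()
        .reset_index()
        .rename(columns={"retained_kg": "biomass_kg"})
    )
    return out


def build_lagged_pairs(
    cots_site_years: pd.DataFrame,
    catch_site_years: pd.DataFrame,
    lag: int,
) -> pd.DataFrame:
    """Inner-join catch at year t with CoTS density (and same-year coral
    cover) at year t + lag, per grid-site.

    ``cots_site_years`` must already be duplicate-resolved: repeated
    (grid_site, year) keys in either input raise, since that violates the
    upstream contract.
    """
    if not 1 <= int(lag) <= 6:
        raise ValueError(f"lag must be between 1 and 6, got {lag}")
    for name, df in (("CoTS", cots_site_years), ("catch", catch_site_years)):
        if df.duplicated(subset=["grid_site", "year"]).any():
            raise ValueError(
                f"{name} table has duplicate (grid_site, year) rows; "
                "resolve duplicates upstream first"
            )
    catch = catch_site_years.rename(columns={"year": "catch_year"}).copy()
    catch["cots_year"] = catch["catch_year"] + int(lag)
    cots = cots_site_years.rename(columns={"year": "cots_year"})
    merged = catch.merge(cots, on=["grid_site", "cots_year"], how="inner")
    merged["lag"] = int(lag)
    cols = [
        "grid_site", "catch_year", "lag", "cots_year",
        "cots_density", "coral_cover", "biomass_kg",
    ]
    return merged[cols].sort_values(["grid_site", "catch_year"], ignore_index=True)


def fish_density_per_1000m2(count) -> float | np.ndarray:
    """Raw belt count (250 m²) to density per 1000 m²."""
    return np.multiply(count, 1000.0 / BELT_AREA_M2)


def biomass_from_length(length_cm, a: float, b: float):
    """Length-weight mass in grams: ``a * length**b``."""
    length = np.asarray(length_cm, dtype=float)
    if a <= 0:
        raise ValueError("length-weight coefficient a must be positive")
    if np.any(length <= 0):
        raise ValueError("lengths must be positive")
    out = a * length**b
    return float(out) if out.ndim == 0 else out


def parse_lengths(s) -> np.ndarray:
    """Decode a ';'-joined length string from the transect CSV."""
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return np.empty(0)
    return np.array([float(v) for v in str(s).split(";")])


def site_mean_length(
    transects: pd.DataFrame,
    *,
    audit: AuditLog | None = None,
) -> pd.DataFrame:
    """Mean total length (cm) pooled over individuals within each
    reef-site-year-group — a flat pool over fish, not a mean of transect
    means.  Site-years with no measured fish are excluded and logged.
    """
    rows = []
    keys = ["reef_pair_id", "reef_id", "zoning", "site", "year", "group"]
    for key, grp in transects.groupby(keys, sort=True):
        lengths = np.concatenate([parse_lengths(s) for s in grp["lengths"]])
        if lengths.size == 0:
            if audit is not None:
                audit.record("exclude_no_lengths", **dict(zip(keys, key)))
            continue
        rows.append(dict(zip(keys, key)) | {"mean_length_cm": float(lengths.mean())})
    return pd.DataFrame(rows)


def reserve_site_table(
    transects: pd.DataFrame,
    length_weight: dict[str, tuple[float, float]],
    *,
    audit: AuditLog | None = None,
) -> pd.DataFrame:
    """Site-level responses for the reserve-effect models.

    For each reef-site-year-group: density per 1000 m² (mean over
    transects of count x 4), standing biomass in kg per 1000 m² (mean
    over transects of the summed length-weight masses, scaled to 1000 m²)
    and the pooled mean length.  ``length_weight`` maps group -> (a, b)
    with mass in grams at length in cm.
    """
    keys = ["reef_pair_id", "reef_id", "zoning", "site", "year", "group"]
    rows = []
    for key, grp in transects.groupby(keys, sort=True):
        group = key[-1]
        if group not in length_weight:
            raise KeyError(f"no length-weight coefficients for group {group!r}")
        a, b = length_weight[group]
        dens = float(np.mean(fish_density_per_1000m2(grp["count"].to_numpy(float))))
        masses = [
            biomass_from_length(parse_lengths(s), a, b).sum() if s else 0.0
            for s in grp["lengths"].fillna("")
        ]
        biom = float(np.mean(masses) * (1000.0 / BELT_AREA_M2) / 1000.0)  # kg/1000 m²
        lengths = np.concatenate([parse_lengths(s) for s in grp["lengths"]])
        rows.append(
            dict(zip(keys, key))
            | {
                "density_per_1000m2": dens,
                "biomass_kg_per_1000m2": biom,
                "mean_length_cm": float(lengths.mean()) if lengths.size else np.nan,
                "unfished": 1.0 if key[2] == "closed" else 0.0,
            }
        )
        if lengths.size == 0 and audit is not None:
            audit.record("no_lengths_for_mean", **dict(zip(keys, key)))
    return pd.DataFrame(rows)


def pairwise_lag_correlations(
    catch: pd.DataFrame,
    cots_site_years: pd.DataFrame | None = None,
    lags=range(1, 7),
    groups: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Pearson correlations of site-year log-catch between fish groups,
    per time lag, over the site-years entering each lag's paired dataset.

    Zero-variance series give an undefined r, reported as missing with a
    warning.  Returns a tidy table (lag, group_a, group_b, pearson_r, n).
    """
    if groups is None:
        groups = tuple(sorted(catch["group"].unique()))
    wide = catch.pivot_table(
        index=["grid_site", "year"], columns="group", values="retained_kg",
        aggfunc="sum", fill_value=0.0,
    )
    rows = []
    for lag in lags:
        sub = wide
        if cots_site_years is not None:
            keys = {
                (s, int(y) - int(lag))
                for s, y in zip(cots_site_years["grid_site"], cots_site_years["year"])
            }
            mask = [idx in keys for idx in sub.index]
            sub = sub[mask]
        logc = np.log1p(sub)
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                xa, xb = logc[ga].to_numpy(), logc[gb].to_numpy()
                if len(xa) < 2 or np.std(xa) == 0 or np.std(xb) == 0:
                    warnings.warn(
                        f"undefined correlation for ({ga}, {gb}) at lag {lag}: "
                        "zero variance or too few points",
                        UserWarning,
                    )
                    r = np.nan
                else:
                    r = float(np.corrcoef(xa, xb)[0, 1])
                rows.append((int(lag), ga, gb, r, len(xa)))
    return pd.DataFrame(rows, columns=["lag", "group_a", "group_b", "pearson_r", "n"])
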