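"""Synthetic reef worlds: grid-sites, catches, manta tows, fish transects.

The real monitoring and fisheries data behind these analyses are held by
their custodians and cannot be redistributed, so this module generates
tables with the same schemas and the statistical structure the analyses
assume: zero-heavy site-year CoTS densities with a lagged positive
dependence on retained catch, tow-level overdispersed counts with very
large reef-year variance, zoning multipliers on fish density and length,
coral-cover covariation, and strong cross-group catch correlations.

Every table is reproducible from a single integer seed through a
hierarchical seed-spawning scheme: each table draws from its own child
generator, so regenerating one table never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STUDY_GROUPS",
    "FISHERIES",
    "WorldConfig",
    "TruthParams",
    "simulate_catch_tables",
    "simulate_cots_surveys",
    "simulate_fish_transects",
    "simulate_paired_site_years",
    "simulate_reserve_site_values",
    "write_world",
    "write_truth",
    "read_truth",
]

#: The six fish groups whose biomass removal is modelled: three families,
#: one family subset (two emperor species) and the coral-trout complex.
STUDY_GROUPS = (
    "Labridae",
    "Lethrinidae",
    "Lethrinus miniatus/nebulosus",
    "Lutjanidae",
    "Serranidae",
    "Plectropomus/Variola",
)

FISHERIES = ("commercial_line", "commercial_net", "commercial_trawl", "charter")

#: Longest catch-to-CoTS time lag considered anywhere in the analyses.
MAX_LAG = 6

# single source of truth for the cover-category midpoint table
from .prep import COVER_CATEGORY_MAP, COVER_CATEGORY_ORDER

_MIDPOINT_CODES = np.array(COVER_CATEGORY_ORDER)
_MIDPOINT_VALUES = np.array([COVER_CATEGORY_MAP[c] for c in COVER_CATEGORY_ORDER])


def _default_correlation() -> np.ndarray:
    """Cross-group log-catch correlation: strong coral trout–Serranidae and
    emperor-species–Lethrinidae coupling, moderate elsewhere."""
    g = list(STUDY_GROUPS)
    r = np.full((6, 6), 0.5)
    np.fill_diagonal(r, 1.0)
    i_ct, i_se = g.index("Plectropomus/Variola"), g.index("Serranidae")
    i_lm, i_le = g.index("Lethrinus miniatus/nebulosus"), g.index("Lethrinidae")
    r[i_ct, i_se] = r[i_se, i_ct] = 0.95
    r[i_lm, i_le] = r[i_le, i_lm] = 0.92
    return r


def _default_multipliers() -> dict:
    """Per-group zoning fold effects on transect density and fish length.

    Chosen so the implied standing-biomass folds (density x length^3 for
    cubic length-weight scaling) span roughly 1.4-2.1 across groups, with
    the wrasse effect weakest and the coral-trout effect strongest.
    """
    return {
        "Labridae": {"density": 1.25, "length": 1.04},
        "Lethrinidae": {"density": 1.30, "length": 1.12},
        "Lethrinus miniatus/nebulosus": {"density": 1.35, "length": 1.15},
        "Lutjanidae": {"density": 1.30, "length": 1.08},
        "Serranidae": {"density": 1.35, "length": 1.12},
        "Plectropomus/Variola": {"density": 1.40, "length": 1.13},
    }


@dataclass
class WorldConfig:
    """Shape of a synthetic survey world.

    Defaults mirror the study's sampling effort: 157 logbook grid-sites,
    reporting years 1990-2018, roughly a third of reefs zoned closed, 15
    belt transects per reef per survey year, and about 47 two-minute
    manta tows per reef-year.
    """

    n_grid_sites: int = 157
    reefs_per_site: int = 2
    years: tuple[int, int] = (1990, 2018)
    fish_groups: tuple[str, ...] = STUDY_GROUPS
    frac_unfished: float = 1.0 / 3.0
    tows_per_reef_year: int = 47
    transects_per_reef: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_grid_sites < 1 or self.reefs_per_site < 1:
            raise ValueError("counts must be >= 1")
        if self.transects_per_reef < 1:
            raise ValueError("transects_per_reef must be >= 1")
        if self.tows_per_reef_year < 0:
            raise ValueError("tows_per_reef_year must be >= 0")
        if not 0.0 <= self.frac_unfished <= 1.0:
            raise ValueError("frac_unfished must lie in [0, 1]")
        if self.years[1] < self.years[0]:
            raise ValueError("year range is empty")
        self.fish_groups = tuple(self.fish_groups)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def grid_sites(self) -> list[str]:
        return [f"S{i:03d}" for i in range(1, self.n_grid_sites + 1)]


@dataclass
class TruthParams:
    """Generative parameters — the ground truth for recovery studies.

    The headline fields default to the study's central estimates used as
    simulation truth: a 2.8-fold open-zoning ratio, coral-cover slope
    -0.45, and reef-year intercept SD 3.77 on the log scale.
    """

    # lagged catch effects on CoTS density, log-log scale: {(group, lag): b}
    biomass_slopes: dict = field(default_factory=dict)
    # hurdle site-year density model (generative twin)
    hurdle_zero_intercept: float = 0.4
    coral_slope_zero: float = 0.5
    hurdle_pos_intercept: float = float(np.log(0.1))
    coral_slope_pos: float = -0.45
    hurdle_gamma_shape: float = 0.8
    sigma_site: float = 0.5
    # tow-level negative-binomial model (generative twin)
    cots_log_intercept: float = float(np.log(0.05))
    zoning_log_ratio: float = float(np.log(2.8))
    coral_slope_cots: float = -0.45
    sigma_reefyear: float = 3.77
    nb_dispersion: float = 0.5
    # reserve effects on fish
    zoning_fish_multipliers: dict = field(default_factory=_default_multipliers)
    # catch generation
    catch_correlation: np.ndarray = field(default_factory=_default_correlation)
    log_catch_means: dict = field(
        default_factory=lambda: {
            "Labridae": float(np.log(100.0)),
            "Lethrinidae": float(np.log(1200.0)),
            "Lethrinus miniatus/nebulosus": float(np.log(800.0)),
            "Lutjanidae": float(np.log(600.0)),
            "Serranidae": float(np.log(1500.0)),
            "Plectropomus/Variola": float(np.log(3000.0)),
        }
    )
    log_catch_sd: float = 1.0
    fishery_shares: dict = field(
        default_factory=lambda: {
            "commercial_line": 0.70,
            "commercial_net": 0.10,
            "commercial_trawl": 0.05,
            "charter": 0.15,
        }
    )
    # coral cover generation (Beta latent, snapped to category midpoints)
    cover_mean: float = 0.30
    cover_concentration: float = 8.0
    tow_cover_concentration: float = 40.0
    # fish transect generation
    transect_count_mean: float = 5.0
    transect_count_dispersion: float = 1.5
    length_log_mean: float = float(np.log(35.0))
    length_log_sd: float = 0.25

    def validate(self, groups=STUDY_GROUPS) -> None:
        if self.sigma_reefyear <= 0 or self.sigma_site <= 0:
            raise ValueError("hierarchical SDs must be positive")
        if self.nb_dispersion <= 0 or self.hurdle_gamma_shape <= 0:
            raise ValueError("dispersion and shape must be positive")
        for g, m in self.zoning_fish_multipliers.items():
            if m["density"] <= 0 or m["length"] <= 0:
                raise ValueError(f"zoning multipliers for {g!r} must be positive")
        r = np.asarray(self.catch_correlation, float)
        n = len(groups)
        if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] < n:
            raise ValueError(
                f"correlation matrix must be square covering the {n} groups, "
                f"got shape {r.shape}"
            )
        r = r[:n, :n]
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        eig = np.linalg.eigvalsh(r)
        if eig.min() < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite: "
                f"smallest eigenvalue {eig.min():.6g}"
            )

    def slope(self, group: str, lag: int) -> float:
        return float(self.biomass_slopes.get((group, lag), 0.0))

    @staticmethod
    def reference_slopes() -> dict:
        """A truth scenario echoing the reported lag pattern: emperor
        effects at short lags, rockcod/coral-trout effects at lag 4,
        no wrasse effect."""
        b = {}
        for g in ("Lethrinidae", "Lethrinus miniatus/nebulosus"):
            b[(g, 1)] = 0.3
            b[(g, 2)] = 0.3
        b[("Lutjanidae", 2)] = 0.3
        b[("Serranidae", 4)] = 0.3
        b[("Plectropomus/Variola", 4)] = 0.3
        return b


def _table_rngs(config: WorldConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    keys = ("catch", "cots", "fish", "paired")
    return {k: np.random.default_rng(s) for k, s in zip(keys, children)}


# ---------------------------------------------------------------------------
# catch
# ---------------------------------------------------------------------------


def simulate_catch_tables(config: WorldConfig, truth: TruthParams) -> pd.DataFrame:
    """Retained-catch table: one row per grid-site x year x group x fishery.

    Log total catch per site-year is multivariate normal across groups
    with the configured correlation matrix; fishery rows split each total
    by fixed shares, so the site-year aggregate preserves the correlation
    exactly.  Years run from ``MAX_LAG`` years before the configured
    start so the longest lag is always coverable.
    """
    truth.validate(config.fish_groups)
    rng = _table_rngs(config)["catch"]
    groups = list(config.fish_groups)
    n_g = len(groups)
    r = np.asarray(truth.catch_correlation, float)[:n_g, :n_g]
    # eigenvalue-based factor (cholesky would reject the PSD boundary)
    w, v = np.linalg.eigh(r)
    fac = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    years = list(range(config.years[0] - MAX_LAG, config.years[1] + 1))
    sites = config.grid_sites()
    mu = np.array([truth.log_catch_means.get(g, np.log(500.0)) for g in groups])

    z = rng.standard_normal((len(sites) * len(years), n_g)) @ fac.T
    log_catch = mu + truth.log_catch_sd * z
    total = np.exp(log_catch)

    site_col = np.repeat(sites, len(years))
    year_col = np.tile(years, len(sites))
    frames = []
    for j, g in enumerate(groups):
        for f in FISHERIES:
            share = truth.fishery_shares.get(f, 0.0)
            frames.append(
                pd.DataFrame(
                    {
                        "grid_site": site_col,
                        "year": year_col,
                        "fishery": f,
                        "group": g,
                        "retained_kg": total[:, j] * share,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["grid_site", "year", "group", "fishery"], ignore_index=True
    )


def _aggregate_catch_wide(catch: pd.DataFrame) -> pd.DataFrame:
    """Site-year x group totals across fisheries (wide)."""
    return catch.pivot_table(
        index=["grid_site", "year"],
        columns="group",
        values="retained_kg",
        aggfunc="sum",
        fill_value=0.0,
    )


# ---------------------------------------------------------------------------
# manta-tow CoTS surveys
# ---------------------------------------------------------------------------


def _snap_cover(p: np.ndarray) -> np.ndarray:
    """Snap latent cover proportions to the nearest category midpoint code."""
    idx = np.argmin(np.abs(p[:, None] - _MIDPOINT_VALUES[None, :]), axis=1)
    return _MIDPOINT_CODES[idx]


def _assign_reefs(config: WorldConfig, rng: np.random.Generator):
    """Reef ids, their grid-sites, and zoning (closed = no-take reserve)."""
    reef_ids, reef_sites = [], []
    for s in config.grid_sites():
        for k in range(1, config.reefs_per_site + 1):
            reef_ids.append(f"{s}-R{k}")
            reef_sites.append(s)
    n = len(reef_ids)
    n_closed = int(round(config.frac_unfished * n))
    closed = np.zeros(n, bool)
    closed[rng.permutation(n)[:n_closed]] = True
    return np.array(reef_ids), np.array(reef_sites), closed


def simulate_cots_surveys(
    config: WorldConfig, truth: TruthParams, catch: pd.DataFrame
) -> pd.DataFrame:
    """Manta-tow table: tow-level CoTS counts and coral-cover codes.

    Tow counts are negative binomial with log-mean
    ``b0 + b1*[open] + b2*cover + zeta(reef-year) + sum_b b(g,x) * log1p(catch)``,
    ``zeta ~ Normal(0, sigma_reefyear)``.  Zeros arise from the count
    process itself — no separate inflation component.
    """
    truth.validate(config.fish_groups)
    rng = _table_rngs(config)["cots"]
    reef_ids, reef_sites, closed = _assign_reefs(config, rng)
    years = config.year_list
    if config.tows_per_reef_year == 0:
        return pd.DataFrame(
            columns=[
                "reef_id", "grid_site", "year", "tow_index",
                "cots_count", "cover_code", "zoning",
            ]
        )

    agg = _aggregate_catch_wide(catch)
    catch_years = agg.index.get_level_values("year")
    first_catch_year = int(catch_years.min())
    active = [(g, x, b) for (g, x), b in truth.biomass_slopes.items() if b != 0.0]
    for y in years:
        for g, x, b in active:
            if y - x < first_catch_year:
                raise ValueError(
                    f"lag {x} for survey year {y} needs catch data for "
                    f"{y - x}, before the first catch year {first_catch_year}"
                )

    n_reefs, n_years, n_tows = len(reef_ids), len(years), config.tows_per_reef_year
    n_ry = n_reefs * n_years

    # reef-year structure
    zeta = rng.normal(0.0, truth.sigma_reefyear, n_ry)
    a = truth.cover_mean * truth.cover_concentration
    b_ = (1 - truth.cover_mean) * truth.cover_concentration
    cover_latent = rng.beta(a, b_, n_ry)

    # lagged catch term per site-year; log-catch is centred per group so
    # the slopes act on catch *variation* and the intercept keeps its
    # meaning as density at group-average catch
    catch_term = np.zeros(n_ry)
    if active:
        mean_log = {
            g: float(np.log1p(agg[g]).mean()) for g in agg.columns
        }
        lut = {}
        for (site, yr), row in agg.iterrows():
            lut[(site, yr)] = row
        k = 0
        for i in range(n_reefs):
            for y in years:
                t = 0.0
                for g, x, b in active:
                    row = lut.get((reef_sites[i], y - x))
                    kg = float(row[g]) if row is not None and g in row else 0.0
                    t += b * (np.log1p(kg) - mean_log.get(g, 0.0))
                catch_term[k] = t
                k += 1

    open_flag = np.repeat(~closed, n_years).astype(float)
    log_mu_ry = (
        truth.cots_log_intercept
        + truth.zoning_log_ratio * open_flag
        + zeta
        + catch_term
    )

    # tow level
    tow_latent = np.repeat(cover_latent, n_tows)
    kappa = truth.tow_cover_concentration
    tow_cover = rng.beta(
        np.clip(tow_latent, 1e-3, 1 - 1e-3) * kappa,
        np.clip(1 - tow_latent, 1e-3, 1 - 1e-3) * kappa,
    )
    codes = _snap_cover(tow_cover)
    cover_prop = _MIDPOINT_VALUES[
        np.argmin(np.abs(tow_cover[:, None] - _MIDPOINT_VALUES[None, :]), axis=1)
    ]
    log_mu = np.repeat(log_mu_ry, n_tows) + truth.coral_slope_cots * cover_prop
    with np.errstate(over="ignore"):
        mu = np.exp(np.clip(log_mu, -30.0, 12.0))  # cap guards astronomically rare tails
    phi = truth.nb_dispersion
    counts = rng.negative_binomial(phi, phi / (phi + mu))

    return pd.DataFrame(
        {
            "reef_id": np.repeat(reef_ids, n_years * n_tows),
            "grid_site": np.repeat(reef_sites, n_years * n_tows),
            "year": np.tile(np.repeat(years, n_tows), n_reefs),
            "tow_index": np.tile(np.arange(1, n_tows + 1), n_ry),
            "cots_count": counts,
            "cover_code": codes,
            "zoning": np.repeat(
                np.where(closed, "closed", "open"), n_years * n_tows
            ),
        }
    )


# ---------------------------------------------------------------------------
# fish belt transects
# ---------------------------------------------------------------------------


def simulate_fish_transects(
    config: WorldConfig,
    truth: TruthParams,
    years: list[int] | None = None,
    n_pairs: int | None = None,
) -> pd.DataFrame:
    """Belt-transect table for paired fished/unfished reefs.

    One reef pair per grid-site (one reef open, one closed), surveyed
    biennially by default.  Counts per 250 m² belt are negative binomial;
    individual total lengths are lognormal.  Unfished reefs carry the
    configured per-group multipliers on count and length, so biomass fold
    effects emerge downstream through the length-weight computation.
    """
    truth.validate(config.fish_groups)
    rng = _table_rngs(config)["fish"]
    if n_pairs is None:
        n_pairs = config.n_grid_sites
    if years is None:
        years = list(range(config.years[0], config.years[1] + 1, 2))

    n_sites = 3
    per_site = max(1, config.transects_per_reef // n_sites)
    rows = []
    for p in range(1, n_pairs + 1):
        pair = f"P{p:03d}"
        for zoning in ("open", "closed"):
            reef = f"{pair}-{'F' if zoning == 'open' else 'U'}"
            for y in years:
                for t_idx in range(config.transects_per_reef):
                    site = min(t_idx // per_site, n_sites - 1) + 1
                    transect = t_idx % per_site + 1
                    for g in config.fish_groups:
                        mult = truth.zoning_fish_multipliers.get(
                            g, {"density": 1.0, "length": 1.0}
                        )
                        dmult = mult["density"] if zoning == "closed" else 1.0
                        lmult = mult["length"] if zoning == "closed" else 1.0
                        mean = truth.transect_count_mean * dmult
                        phi = truth.transect_count_dispersion
                        count = int(rng.negative_binomial(phi, phi / (phi + mean)))
                        lengths = lmult * rng.lognormal(
                            truth.length_log_mean, truth.length_log_sd, count
                        )
                        rows.append(
                            (
                                pair, reef, zoning, site, y, transect, g, count,
                                ";".join(f"{v:.2f}" for v in lengths),
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "reef_pair_id", "reef_id", "zoning", "site", "year",
            "transect", "group", "count", "lengths",
        ],
    )


# ---------------------------------------------------------------------------
# direct model-family generators (for recovery studies)
# ---------------------------------------------------------------------------


def simulate_paired_site_years(
    config: WorldConfig,
    truth: TruthParams,
    group: str,
    lag: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Paired site-year observations drawn directly from the hurdle-gamma
    site-year process (the lag-analysis model family).

    Site intercepts are Normal(0, sigma_site); the zero probability follows
    the logit-linear zero component and positive densities are gamma with
    log-mean ``intercept + coral_slope*cover + b(g, lag)*log1p(kg) + u_site``.
    Used for parameter-recovery studies where data and model share a family.
    """
    truth.validate(config.fish_groups)
    if rng is None:
        rng = _table_rngs(config)["paired"]
    sites = config.grid_sites()
    years = config.year_list
    b = truth.slope(group, lag)

    u_site = rng.normal(0.0, truth.sigma_site, len(sites))
    n = len(sites) * len(years)
    site_idx = np.repeat(np.arange(len(sites)), len(years))
    a = truth.cover_mean * truth.cover_concentration
    b_beta = (1 - truth.cover_mean) * truth.cover_concentration
    cover = rng.beta(a, b_beta, n)
    mu_c = truth.log_catch_means.get(group, np.log(500.0))
    biomass = np.exp(rng.normal(mu_c, truth.log_catch_sd, n))
    log_b = np.log1p(biomass)

    eta_zero = truth.hurdle_zero_intercept + truth.coral_slope_zero * cover
    p_zero = 1.0 / (1.0 + np.exp(-eta_zero))
    eta_pos = (
        truth.hurdle_pos_intercept
        + truth.coral_slope_pos * cover
        + b * log_b
        + u_site[site_idx]
    )
    shape = truth.hurdle_gamma_shape
    y = rng.gamma(shape, np.exp(eta_pos) / shape)
    y[rng.random(n) < p_zero] = 0.0

    catch_year = np.tile(years, len(sites))
    return pd.DataFrame(
        {
            "grid_site": np.repeat(sites, len(years)),
            "catch_year": catch_year - lag,
            "lag": lag,
            "cots_year": catch_year,
            "cots_density": y,
            "coral_cover": cover,
            "biomass_kg": biomass,
        }
    )


def simulate_reserve_site_values(
    *,
    n_pairs: int = 8,
    years: list[int] | None = None,
    family: str = "hurdle_gamma",
    log_fold: float,
    baseline_log: float = 0.0,
    shape: float = 2.0,
    zero_intercept: float = -1.5,
    zero_fold: float = 0.0,
    re_sds: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Site-level responses drawn directly from the reserve model family.

    Generates one value per reef-pair x reef x within-reef site x year
    from a gamma (or hurdle-gamma) process with an unfished log-fold
    effect and random intercepts for site, reef pair, reef and year —
    the exact structure of the reserve-effect models, for recovery runs.
    """
    if years is None:
        years = [2006, 2008, 2010, 2012]
    sds = {"site": 0.25, "reef_pair_id": 0.3, "reef_id": 0.25, "year": 0.2}
    if re_sds:
        sds.update(re_sds)
    rng = np.random.default_rng(seed)

    rows = []
    u_pair = rng.normal(0, sds["reef_pair_id"], n_pairs)
    u_year = {y: rng.normal(0, sds["year"]) for y in years}
    for p in range(n_pairs):
        pair = f"P{p + 1:03d}"
        for zoning in ("open", "closed"):
            reef = f"{pair}-{'F' if zoning == 'open' else 'U'}"
            u_reef = rng.normal(0, sds["reef_id"])
            for s in (1, 2, 3):
                site = f"{reef}-S{s}"
                u_site = rng.normal(0, sds["site"])
                for y in years:
                    unfished = 1.0 if zoning == "closed" else 0.0
                    eta = (
                        baseline_log
                        + log_fold * unfished
                        + u_pair[p]
                        + u_reef
                        + u_site
                        + u_year[y]
                    )
                    val = rng.gamma(shape, np.exp(eta) / shape)
                    if family == "hurdle_gamma":
                        pz = 1.0 / (
                            1.0 + np.exp(-(zero_intercept + zero_fold * unfished))
                        )
                        if rng.random() < pz:
                            val = 0.0
                    rows.append((pair, reef, zoning, unfished, site, y, val))
    return pd.DataFrame(
        rows,
        columns=[
            "reef_pair_id", "reef_id", "zoning", "unfished", "site", "year", "value",
        ],
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_truth(truth: TruthParams, path) -> None:
    d = dataclasses.asdict(truth)
    d["catch_correlation"] = np.asarray(truth.catch_correlation).tolist()
    d["biomass_slopes"] = [
        {"group": g, "lag": x, "slope": v} for (g, x), v in truth.biomass_slopes.items()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_truth(path) -> TruthParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["catch_correlation"] = np.asarray(d["catch_correlation"], float)
    d["biomass_slopes"] = {
        (e["group"], int(e["lag"])): float(e["slope"]) for e in d["biomass_slopes"]
    }
    return TruthParams(**d)


def write_world(config: WorldConfig, truth: TruthParams, outdir) -> dict[str, str]:
    """Generate and write the three observation CSVs plus the truth file."""
    import os

    os.makedirs(outdir, exist_ok=True)
    catch = simulate_catch_tables(config, truth)
    tows = simulate_cots_surveys(config, truth, catch)
    fish = simulate_fish_transects(config, truth)
    paths = {
        "catch": os.path.join(outdir, "catch.csv"),
        "manta_tows": os.path.join(outdir, "manta_tows.csv"),
        "fish_transects": os.path.join(outdir, "fish_transects.csv"),
        "truth": os.path.join(outdir, "truth.yaml"),
    }
    catch.to_csv(paths["catch"], index=False)
    tows.to_csv(paths["manta_tows"], index=False)
    fish.to_csv(paths["fish_transects"], index=False)
    write_truth(truth, paths["truth"])
    return paths
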