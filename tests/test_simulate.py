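"""Synthetic-data generator: determinism, moments, configured structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cotslink.prep import convert_cover_series
from cotslink.simulate import (
    STUDY_GROUPS,
    TruthParams,
    WorldConfig,
    read_truth,
    simulate_catch_tables,
    simulate_cots_surveys,
    simulate_fish_transects,
    simulate_paired_site_years,
    write_truth,
)


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            WorldConfig(n_grid_sites=0)

    def test_year_range_nonempty(self):
        with pytest.raises(ValueError):
            WorldConfig(years=(2005, 2000))

    def test_frac_unfished_bounds(self):
        with pytest.raises(ValueError):
            WorldConfig(frac_unfished=1.5)

    def test_invalid_correlation_names_eigenvalue(self):
        r = np.full((6, 6), 0.99)
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = -0.99  # forces a negative eigenvalue
        truth = TruthParams(catch_correlation=r)
        with pytest.raises(ValueError, match="eigenvalue"):
            truth.validate()

    def test_asymmetric_correlation_rejected(self):
        r = np.eye(6)
        r[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            TruthParams(catch_correlation=r).validate()


class TestDeterminism:
    def test_catch_table_byte_identical(self, tiny_world, truth):
        a = simulate_catch_tables(tiny_world, truth).to_csv(index=False)
        b = simulate_catch_tables(tiny_world, truth).to_csv(index=False)
        assert a == b

    def test_all_tables_reproducible_and_independent(self, tiny_world, truth):
        catch = simulate_catch_tables(tiny_world, truth)
        tows1 = simulate_cots_surveys(tiny_world, truth, catch)
        fish1 = simulate_fish_transects(tiny_world, truth)
        # regenerating one table does not perturb another (child seeds)
        tows2 = simulate_cots_surveys(tiny_world, truth, catch)
        pd.testing.assert_frame_equal(tows1, tows2)
        fish2 = simulate_fish_transects(tiny_world, truth)
        pd.testing.assert_frame_equal(fish1, fish2)

    def test_different_seed_differs(self, tiny_world, truth):
        other = WorldConfig(**{**tiny_world.__dict__, "seed": 12})
        a = simulate_catch_tables(tiny_world, truth)
        b = simulate_catch_tables(other, truth)
        assert not a["retained_kg"].equals(b["retained_kg"])


class TestCatchStructure:
    def _site_year_log_catch(self, catch, group):
        agg = (
            catch[catch["group"] == group]
            .groupby(["grid_site", "year"])["retained_kg"]
            .sum()
        )
        return np.log(agg.to_numpy())

    def test_identity_correlation_gives_near_zero_sample_r(self):
        cfg = WorldConfig(
            n_grid_sites=25, reefs_per_site=1, years=(2000, 2013),
            fish_groups=STUDY_GROUPS[:2], seed=42,
        )
        truth = TruthParams(catch_correlation=np.eye(2))
        catch = simulate_catch_tables(cfg, truth)  # 25 x 20 = 500 site-years
        a = self._site_year_log_catch(catch, STUDY_GROUPS[0])
        b = self._site_year_log_catch(catch, STUDY_GROUPS[1])
        assert len(a) == 500
        r, _ = stats.pearsonr(a, b)
        assert abs(r) < 0.2

    def test_strong_correlation_reproduced(self):
        cfg = WorldConfig(
            n_grid_sites=25, reefs_per_site=1, years=(2000, 2013), seed=7
        )
        catch = simulate_catch_tables(cfg, TruthParams())
        a = self._site_year_log_catch(catch, "Plectropomus/Variola")
        b = self._site_year_log_catch(catch, "Serranidae")
        r, _ = stats.pearsonr(a, b)
        assert r > 0.9

    def test_schema_one_row_per_cell(self, tiny_world, truth):
        catch = simulate_catch_tables(tiny_world, truth)
        n_years = (tiny_world.years[1] - tiny_world.years[0] + 1) + 6  # lag buffer
        expected = tiny_world.n_grid_sites * n_years * 6 * 4
        assert len(catch) == expected
        assert (catch["retained_kg"] >= 0).all()
        assert not catch.duplicated(["grid_site", "year", "group", "fishery"]).any()


class TestCotsSurveys:
    def test_zero_tows_gives_empty_table(self, truth):
        cfg = WorldConfig(
            n_grid_sites=2, years=(2000, 2001), tows_per_reef_year=0, seed=1
        )
        catch = simulate_catch_tables(cfg, truth)
        tows = simulate_cots_surveys(cfg, truth, catch)
        assert len(tows) == 0

    def test_iid_negbin_when_all_effects_off(self):
        cfg = WorldConfig(
            n_grid_sites=10, reefs_per_site=2, years=(2000, 2009),
            tows_per_reef_year=25, seed=5,
        )
        truth = TruthParams(
            sigma_reefyear=1e-9, zoning_log_ratio=0.0, coral_slope_cots=0.0,
            cots_log_intercept=np.log(0.8), nb_dispersion=1.2, biomass_slopes={},
        )
        tows = simulate_cots_surveys(cfg, truth, simulate_catch_tables(cfg, truth))
        counts = tows["cots_count"].to_numpy()
        mu, phi = 0.8, 1.2
        se = np.sqrt((mu + mu**2 / phi) / len(counts))
        assert counts.mean() == pytest.approx(mu, abs=3 * se)
        # variance matches the NB2 closed form at n = 10^4 scale
        assert counts.var() == pytest.approx(mu + mu**2 / phi, rel=0.15)

    def test_zoning_ratio_recovered_in_means(self):
        cfg = WorldConfig(
            n_grid_sites=40, reefs_per_site=2, years=(2000, 2009),
            tows_per_reef_year=20, frac_unfished=0.5, seed=9,
        )
        truth = TruthParams(
            sigma_reefyear=1e-9, coral_slope_cots=0.0,
            cots_log_intercept=np.log(0.5), biomass_slopes={},
        )
        tows = simulate_cots_surveys(cfg, truth, simulate_catch_tables(cfg, truth))
        means = tows.groupby("zoning")["cots_count"].mean()
        assert means["open"] / means["closed"] == pytest.approx(2.8, rel=0.1)

    def test_cover_codes_all_valid(self, tiny_world, truth):
        tows = simulate_cots_surveys(
            tiny_world, truth, simulate_catch_tables(tiny_world, truth)
        )
        convert_cover_series(tows["cover_code"])  # raises on an unknown code

    def test_truncated_catch_names_offending_year(self, tiny_world):
        truth = TruthParams(biomass_slopes={("Lethrinidae", 3): 0.3})
        catch = simulate_catch_tables(tiny_world, truth)
        truncated = catch[catch["year"] >= tiny_world.years[0]]
        with pytest.raises(ValueError, match=str(tiny_world.years[0])):
            simulate_cots_surveys(tiny_world, truth, truncated)


class TestFishTransects:
    def test_row_bookkeeping_56_pairs(self, truth):
        cfg = WorldConfig(
            n_grid_sites=56, years=(2006, 2020), transects_per_reef=15, seed=2,
            fish_groups=("Serranidae",),
        )
        years = list(range(2006, 2021, 2))  # 8 biennial years
        fish = simulate_fish_transects(cfg, truth, years=years)
        assert len(fish) == 56 * 2 * 15 * 8
        per_reef_year = fish.groupby(["reef_id", "year"]).size()
        assert (per_reef_year == 15).all()
        assert set(fish["site"].unique()) == {1, 2, 3}
        assert set(fish["transect"].unique()) == {1, 2, 3, 4, 5}

    def test_null_multiplier_leaves_zones_equal(self):
        cfg = WorldConfig(
            n_grid_sites=40, years=(2006, 2013), transects_per_reef=10,
            fish_groups=("Serranidae",), seed=3,
        )
        truth = TruthParams(
            zoning_fish_multipliers={"Serranidae": {"density": 1.0, "length": 1.0}}
        )
        fish = simulate_fish_transects(cfg, truth)
        m = fish.groupby("zoning")["count"].mean()
        pooled_se = fish["count"].std() * np.sqrt(2 / (len(fish) / 2))
        assert abs(m["open"] - m["closed"]) < 3 * pooled_se

    def test_length_multiplier_shifts_mean_length(self):
        cfg = WorldConfig(
            n_grid_sites=60, years=(2006, 2013), transects_per_reef=10,
            fish_groups=("Serranidae",), seed=4,
        )
        truth = TruthParams(
            zoning_fish_multipliers={"Serranidae": {"density": 1.0, "length": 1.2}}
        )
        fish = simulate_fish_transects(cfg, truth)
        def mean_len(z):
            vals = [
                float(v)
                for s in fish[fish["zoning"] == z]["lengths"]
                if s
                for v in s.split(";")
            ]
            return np.mean(vals)
        assert mean_len("closed") / mean_len("open") == pytest.approx(1.2, rel=0.02)


class TestPairedGenerator:
    def test_schema_and_invariants(self, tiny_world, truth):
        df = simulate_paired_site_years(tiny_world, truth, "Lethrinidae", 2)
        assert (df["cots_year"] - df["catch_year"] == 2).all()
        assert (df["cots_density"] >= 0).all()
        assert df["coral_cover"].between(0, 1).all()
        assert len(df) == tiny_world.n_grid_sites * len(tiny_world.year_list)

    def test_zero_heavy(self, tiny_world, truth):
        df = simulate_paired_site_years(tiny_world, truth, "Lethrinidae", 1)
        assert (df["cots_density"] == 0).mean() > 0.3


def test_truth_yaml_roundtrip(tmp_path, truth):
    truth.biomass_slopes = TruthParams.reference_slopes()
    p = tmp_path / "truth.yaml"
    write_truth(truth, p)
    back = read_truth(p)
    assert back.biomass_slopes == truth.biomass_slopes
    assert back.sigma_reefyear == truth.sigma_reefyear
    np.testing.assert_allclose(back.catch_correlation, truth.catch_correlation)


def test_default_multipliers_span_the_reserve_fold_band(truth):
    # density x length^3 (cubic length-weight) spans roughly 1.4-2.1
    folds = [
        m["density"] * m["length"] ** 3
        for m in truth.zoning_fish_multipliers.values()
    ]
    assert min(folds) > 1.3 and max(folds) < 2.2
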