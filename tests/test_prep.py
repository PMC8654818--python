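"""Data preparation: exact bookkeeping against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cotslink.prep import (
    COVER_CATEGORY_MAP,
    COVER_CATEGORY_ORDER,
    AuditLog,
    aggregate_catch,
    aggregate_catch_table,
    biomass_from_length,
    build_lagged_pairs,
    convert_cover_category,
    cots_density_per_minute,
    fish_density_per_1000m2,
    pairwise_lag_correlations,
    parse_lengths,
    resolve_duplicates,
    site_mean_length,
    site_year_cots_from_tows,
)

SETTINGS = settings(max_examples=30, deadline=None, derandomize=True)


class TestCoverConversion:
    @pytest.mark.parametrize(
        "code,expected", [("3", 0.4), ("0", 0.0), ("5U", 0.9375), ("1L", 0.025)]
    )
    def test_printed_cells(self, code, expected):
        assert convert_cover_category(code) == expected

    def test_unknown_code_named(self):
        with pytest.raises(KeyError, match="'9X'"):
            convert_cover_category("9X")

    def test_complete_and_injective(self):
        assert len(COVER_CATEGORY_MAP) == 16
        assert len(set(COVER_CATEGORY_MAP.values())) == 16
        assert all(0.0 <= v <= 1.0 for v in COVER_CATEGORY_MAP.values())

    def test_order_preserving(self):
        vals = [convert_cover_category(c) for c in COVER_CATEGORY_ORDER]
        assert vals == sorted(vals)


class TestDensity:
    @pytest.mark.parametrize(
        "counts,expected", [([4], 2.0), ([0, 0, 0], 0.0), ([1, 2, 3, 0, 4], 1.0)]
    )
    def test_examples(self, counts, expected):
        assert cots_density_per_minute(counts) == pytest.approx(expected)

    def test_empty_tow_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cots_density_per_minute([])

    @given(c=st.integers(0, 50), k=st.integers(1, 20))
    @SETTINGS
    def test_replicated_tows_halve_the_count(self, c, k):
        assert cots_density_per_minute([c] * k) == pytest.approx(c / 2.0)


def _reef_table(rows):
    return pd.DataFrame(
        rows, columns=["grid_site", "year", "zoning", "reef_id", "cots_density", "coral_cover"]
    )


class TestResolveDuplicates:
    def test_closed_dropped_when_both_zonings(self):
        t = _reef_table(
            [
                ("S1", 2000, "open", "A", 1.0, 0.2),
                ("S1", 2000, "closed", "B", 5.0, 0.4),
            ]
        )
        out = resolve_duplicates(t)
        assert len(out) == 1
        assert out.loc[0, "cots_density"] == 1.0
        assert out.loc[0, "zoning"] == "open"

    def test_same_zoning_reefs_averaged(self):
        t = _reef_table(
            [
                ("S1", 2000, "open", "A", 1.0, 0.2),
                ("S1", 2000, "open", "B", 3.0, 0.4),
            ]
        )
        out = resolve_duplicates(t)
        assert out.loc[0, "cots_density"] == pytest.approx(2.0)
        assert out.loc[0, "coral_cover"] == pytest.approx(0.3)

    def test_single_record_unchanged(self):
        t = _reef_table([("S1", 2000, "closed", "A", 1.5, 0.2)])
        out = resolve_duplicates(t)
        assert out.loc[0, "cots_density"] == 1.5

    def test_open_only_stream_drops_closed_site_years(self):
        t = _reef_table(
            [
                ("S1", 2000, "closed", "A", 1.0, 0.2),
                ("S2", 2000, "open", "B", 2.0, 0.3),
            ]
        )
        audit = AuditLog()
        out = resolve_duplicates(t, open_only=True, audit=audit)
        assert list(out["grid_site"]) == ["S2"]
        assert any(e["action"] == "drop_closed_only_site_year" for e in audit.events)

    def test_idempotent_on_own_output(self):
        t = _reef_table(
            [
                ("S1", 2000, "open", "A", 1.0, 0.2),
                ("S1", 2000, "open", "B", 3.0, 0.4),
                ("S2", 2001, "closed", "C", 0.0, 0.1),
            ]
        )
        once = resolve_duplicates(t)
        again = resolve_duplicates(once.assign(reef_id="merged"))
        core = ["grid_site", "year", "zoning", "cots_density", "coral_cover"]
        pd.testing.assert_frame_equal(
            once[core].reset_index(drop=True), again[core].reset_index(drop=True)
        )

    @given(st.data())
    @SETTINGS
    def test_never_grows_and_open_only_has_no_closed(self, data):
        n = data.draw(st.integers(1, 25))
        rows = [
            (
                f"S{data.draw(st.integers(1, 4))}",
                data.draw(st.integers(2000, 2003)),
                data.draw(st.sampled_from(["open", "closed"])),
                f"R{i}",
                data.draw(st.floats(0, 10, allow_nan=False)),
                data.draw(st.floats(0, 1, allow_nan=False)),
            )
            for i in range(n)
        ]
        t = _reef_table(rows)
        out = resolve_duplicates(t, open_only=True)
        assert len(out) <= len(t)
        assert not (out["zoning"] == "closed").any()
        assert not out.duplicated(["grid_site", "year"]).any()


def _catch(rows):
    return pd.DataFrame(
        rows, columns=["grid_site", "year", "fishery", "group", "retained_kg"]
    )


class TestAggregateCatch:
    def test_sum_across_fisheries(self):
        t = _catch(
            [
                ("S1", 2000, "commercial_line", "Lethrinidae", 100.0),
                ("S1", 2000, "commercial_net", "Lethrinidae", 20.0),
                ("S1", 2000, "charter", "Lethrinidae", 5.0),
            ]
        )
        assert aggregate_catch(t, group="Lethrinidae", grid_site="S1", year=2000) == 125.0

    def test_no_records_is_zero(self):
        assert aggregate_catch(_catch([]), group="Lethrinidae") == 0.0

    def test_duplicate_fishery_rows_summed_with_warning(self):
        t = _catch(
            [
                ("S1", 2000, "commercial_line", "Lethrinidae", 10.0),
                ("S1", 2000, "commercial_line", "Lethrinidae", 7.0),
            ]
        )
        audit = AuditLog()
        with pytest.warns(UserWarning, match="duplicate fishery"):
            total = aggregate_catch(t, group="Lethrinidae", audit=audit)
        assert total == 17.0
        assert audit.events[0]["action"] == "sum_duplicate_fishery_rows"

    def test_negative_mass_rejected(self):
        t = _catch([("S1", 2000, "charter", "Lethrinidae", -1.0)])
        with pytest.raises(ValueError, match="non-negative"):
            aggregate_catch(t, group="Lethrinidae")

    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=1, max_size=8), st.randoms())
    @SETTINGS
    def test_permutation_invariant_and_additive(self, kgs, pyrandom):
        import warnings as _w

        fisheries = ["commercial_line", "commercial_net", "commercial_trawl", "charter"]
        rows = [
            ("S1", 2000, fisheries[i % 4], "Serranidae", kg) for i, kg in enumerate(kgs)
        ]
        t = _catch(rows)
        shuffled = t.sample(frac=1.0, random_state=pyrandom.randint(0, 10**6))
        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)  # duplicate-fishery notices
            assert aggregate_catch(t, group="Serranidae") == pytest.approx(
                aggregate_catch(shuffled, group="Serranidae")
            )
            # additivity over a fishery partition
            parts = sum(
                aggregate_catch(t[t["fishery"] == f], group="Serranidae")
                for f in fisheries
            )
            assert parts == pytest.approx(aggregate_catch(t, group="Serranidae"))


class TestLagPairs:
    def _cots(self, rows):
        return pd.DataFrame(rows, columns=["grid_site", "year", "cots_density", "coral_cover"])

    def _catch_sy(self, rows):
        return pd.DataFrame(rows, columns=["grid_site", "year", "biomass_kg"])

    def test_basic_join(self):
        pairs = build_lagged_pairs(
            self._cots([("A", 2002, 1.0, 0.3)]), self._catch_sy([("A", 2000, 50.0)]), 2
        )
        assert len(pairs) == 1
        assert pairs.loc[0, "catch_year"] == 2000
        assert pairs.loc[0, "cots_year"] == 2002
        assert pairs.loc[0, "lag"] == 2

    def test_wrong_lag_gives_no_pairs(self):
        pairs = build_lagged_pairs(
            self._cots([("A", 2002, 1.0, 0.3)]), self._catch_sy([("A", 2000, 50.0)]), 3
        )
        assert len(pairs) == 0

    def test_lag_out_of_range(self):
        with pytest.raises(ValueError, match="lag"):
            build_lagged_pairs(self._cots([]), self._catch_sy([]), 7)

    def test_duplicate_site_years_violate_contract(self):
        cots = self._cots([("A", 2002, 1.0, 0.3), ("A", 2002, 2.0, 0.3)])
        with pytest.raises(ValueError, match="duplicate"):
            build_lagged_pairs(cots, self._catch_sy([("A", 2000, 1.0)]), 2)

    @given(st.data())
    @SETTINGS
    def test_matches_bruteforce_double_loop(self, data):
        sites = ["A", "B", "C"]
        years = list(range(2000, 2005))
        cots_keys = data.draw(
            st.lists(st.tuples(st.sampled_from(sites), st.sampled_from(years)),
                     unique=True, max_size=10)
        )
        catch_keys = data.draw(
            st.lists(st.tuples(st.sampled_from(sites), st.sampled_from(years)),
                     unique=True, max_size=10)
        )
        lag = data.draw(st.integers(1, 6))
        cots = self._cots([(s, y, 1.0, 0.5) for s, y in cots_keys])
        catch = self._catch_sy([(s, y, 10.0) for s, y in catch_keys])
        got = build_lagged_pairs(cots, catch, lag) if len(cots) and len(catch) else []
        expected = sum(
            1
            for s1, y1 in catch_keys
            for s2, y2 in cots_keys
            if s1 == s2 and y2 - y1 == lag
        )
        assert len(got) == expected


class TestFishMetrics:
    @pytest.mark.parametrize("count,expected", [(10, 40.0), (0, 0.0), (7, 28.0)])
    def test_density_scaling(self, count, expected):
        assert fish_density_per_1000m2(count) == expected

    def test_length_weight_closed_form(self):
        assert biomass_from_length(50.0, 0.01, 3.0) == pytest.approx(1250.0)  # grams

    def test_degenerate_exponent(self):
        for L in (1.0, 17.0, 120.0):
            assert biomass_from_length(L, 0.02, 0.0) == pytest.approx(0.02)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            biomass_from_length(0.0, 0.01, 3.0)

    def test_pooled_mean_not_mean_of_transect_means(self):
        # 1 fish of 10 cm on one transect, 3 fish of 40 cm on another:
        # flat pool = 32.5; mean of transect means would be 25
        t = pd.DataFrame(
            {
                "reef_pair_id": ["P1"] * 2,
                "reef_id": ["R"] * 2,
                "zoning": ["open"] * 2,
                "site": [1, 1],
                "year": [2006] * 2,
                "transect": [1, 2],
                "group": ["Serranidae"] * 2,
                "count": [1, 3],
                "lengths": ["10.00", "40.00;40.00;40.00"],
            }
        )
        out = site_mean_length(t)
        assert out.loc[0, "mean_length_cm"] == pytest.approx(32.5)

    def test_no_lengths_excluded_and_logged(self):
        t = pd.DataFrame(
            {
                "reef_pair_id": ["P1"],
                "reef_id": ["R"],
                "zoning": ["open"],
                "site": [1],
                "year": [2006],
                "transect": [1],
                "group": ["Serranidae"],
                "count": [0],
                "lengths": [""],
            }
        )
        audit = AuditLog()
        out = site_mean_length(t, audit=audit)
        assert len(out) == 0
        assert audit.events[0]["action"] == "exclude_no_lengths"

    def test_parse_lengths_roundtrip(self):
        assert parse_lengths("10.00;20.50").tolist() == [10.0, 20.5]
        assert parse_lengths("").size == 0


class TestCorrelations:
    def _catch_two_series(self, a, b):
        rows = []
        for i, (x, y) in enumerate(zip(a, b)):
            rows.append(("S1", 2000 + i, "commercial_line", "G1", x))
            rows.append(("S1", 2000 + i, "commercial_line", "G2", y))
        return _catch(rows)

    def test_series_vs_itself(self):
        a = [1.0, 5.0, 2.0, 9.0, 4.0]
        t = self._catch_two_series(a, a)
        out = pairwise_lag_correlations(t, lags=[1])
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)

    def test_toy_series_matches_pearson_formula(self):
        a = [1.0, 5.0, 2.0, 9.0, 4.0]
        b = [2.0, 3.0, 7.0, 1.0, 6.0]
        t = self._catch_two_series(a, b)
        out = pairwise_lag_correlations(t, lags=[1])
        expected, _ = stats.pearsonr(np.log1p(a), np.log1p(b))
        assert out.loc[0, "pearson_r"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_missing_with_warning(self):
        t = self._catch_two_series([3.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="zero variance"):
            out = pairwise_lag_correlations(t, lags=[1])
        assert np.isnan(out.loc[0, "pearson_r"])


def test_site_year_table_from_tows(toy_tow_table):
    out = site_year_cots_from_tows(toy_tow_table)
    # reef A, 2000: counts {4, 0} -> density (2 + 0)/2 = 1.0 per minute
    row = out[(out.reef_id == "A") & (out.year == 2000)].iloc[0]
    assert row.cots_density == pytest.approx(1.0)
    assert row.coral_cover == pytest.approx((0.4 + 0.0) / 2)


def test_aggregate_catch_table_groups_only_requested_group():
    t = _catch(
        [
            ("S1", 2000, "commercial_line", "Lethrinidae", 10.0),
            ("S1", 2000, "charter", "Lethrinidae", 5.0),
            ("S1", 2000, "commercial_line", "Serranidae", 99.0),
        ]
    )
    out = aggregate_catch_table(t, "Lethrinidae")
    assert len(out) == 1 and out.loc[0, "biomass_kg"] == 15.0
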