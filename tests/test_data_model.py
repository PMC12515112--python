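"""Capture-table validation, selection filters and history building."""

import numpy as np
import pandas as pd
import pytest

from cesdemog import (
    AGE_ADULT,
    AGE_JUVENILE,
    CaptureTable,
    SelectionCriteria,
    SelectionReport,
    build_histories,
    modal_max_visits,
    read_capture_table,
    select_site_years,
    select_species,
    select_species_site_years,
    write_capture_table,
)
from cesdemog.errors import DataError, SchemaError

from conftest import capture_row, make_table


class TestReadWrite:
    def test_round_trip_is_lossless(self, tmp_path):
        table = make_table(
            [
                capture_row("r1", year=2001, visit=3),
                capture_row("r2", year=2002, visit=5, age=AGE_JUVENILE),
                capture_row("r3", site="S2", year=2001, visit=1),
            ]
        )
        path = tmp_path / "captures.csv"
        write_capture_table(table, path)
        back = read_capture_table(path)
        pd.testing.assert_frame_equal(table.df, back.df)

    def test_unknown_age_class_names_row(self):
        rows = [capture_row("r1"), capture_row("r2")]
        rows[1]["age_class"] = "nestling"
        with pytest.raises(ValueError, match=r"nestling.*\[1\]"):
            make_table(rows)

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="age_class"):
            CaptureTable(pd.DataFrame({"ring_id": ["r1"]}))

    def test_empty_file_with_header_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("ring_id,species,scheme,site,year,visit,age_class\n")
        table = read_capture_table(path)
        assert len(table) == 0

    def test_site_in_two_schemes_rejected(self):
        rows = [capture_row("r1", scheme="A"), capture_row("r2", scheme="B")]
        with pytest.raises(ValueError, match="more than one scheme"):
            make_table(rows)


def _visits_table(site_year_visits, scheme="SC"):
    """site_year_visits: dict (site, year) -> iterable of visit indices."""
    rows = []
    i = 0
    for (site, year), visits in site_year_visits.items():
        for v in visits:
            rows.append(capture_row(f"r{i}", scheme=scheme, site=site, year=year, visit=v))
            i += 1
    return make_table(rows)


class TestModalMaxVisits:
    def test_unique_mode(self):
        sy = {}
        for k in range(10):
            sy[(f"A{k}", 2000)] = range(1, 13)  # 12 visits x10
        sy[("B", 2000)] = range(1, 11)
        sy[("B", 2001)] = range(1, 11)
        table = _visits_table(sy)
        assert modal_max_visits(table, "SC") == 12

    def test_tie_broken_to_larger(self):
        sy = {}
        for k in range(5):
            sy[(f"A{k}", 2000)] = range(1, 11)  # 10 visits x5
            sy[(f"B{k}", 2000)] = range(1, 13)  # 12 visits x5
        table = _visits_table(sy)
        assert modal_max_visits(table, "SC") == 12

    def test_single_site_year(self):
        table = _visits_table({("A", 2000): range(1, 10)})
        assert modal_max_visits(table, "SC") == 9

    def test_absent_scheme_raises(self):
        table = _visits_table({("A", 2000): [1]})
        with pytest.raises(KeyError):
            modal_max_visits(table, "NOPE")


class TestSelectSiteYears:
    def _scheme_with_vmax12(self, extra):
        """A reference site with five 12-visit years fixes V = 12; merge extras."""
        sy = {("REF", 2000 + k): range(1, 13) for k in range(5)}
        sy.update(extra)
        return _visits_table(sy)

    def test_site_with_four_years_excluded(self):
        # site X: 4 fully covered years -> fails the >= 5 years rule
        extra = {("X", 2000 + k): range(1, 13) for k in range(4)}
        table = self._scheme_with_vmax12(extra)
        out, report = select_site_years(table)
        assert "X" not in set(out.df["site"])
        rules = [e for e in report.entries if e["identifier"] == "SC/X"]
        assert rules and "retained years 4 < 5" in rules[0]["rule"]

    def test_site_year_with_adequate_halves_retained(self):
        # 8 visits (>= 2/3 * 12 = 8), 4 per half (>= 1/4 * 12 = 3)
        visits = [1, 2, 3, 4, 7, 8, 9, 10]
        extra = {("X", 2000 + k): visits for k in range(5)}
        table = self._scheme_with_vmax12(extra)
        out, _ = select_site_years(table)
        assert set(out.df[out.df["site"] == "X"]["year"]) == set(range(2000, 2005))

    def test_site_year_lopsided_toward_first_half_excluded(self):
        # 8 visits meets the 2/3 rule, but the second half has only 2 (< 3)
        extra = {("X", 2000 + k): [1, 2, 3, 4, 5, 6, 7, 8] for k in range(5)}
        table = self._scheme_with_vmax12(extra)
        out, report = select_site_years(table)
        assert "X" not in set(out.df["site"])
        assert any("half-season" in e["rule"] for e in report.entries)

    def test_exclusion_plus_retained_conserves_records(self):
        extra = {("X", 2000 + k): range(1, 7) for k in range(5)}
        table = self._scheme_with_vmax12(extra)
        out, report = select_site_years(table)
        assert report.input_records == len(table.df)
        n_excluded_records = len(table.df) - len(out.df)
        assert n_excluded_records == 5 * 6  # site X's records all dropped


class TestSpeciesFilters:
    def _species_counts_table(self, adults, juveniles, species="SP", site="S1", year=2000):
        rows = []
        for i in range(adults):
            rows.append(capture_row(f"{species}a{i}", species=species, site=site, year=year))
        for i in range(juveniles):
            rows.append(
                capture_row(f"{species}j{i}", species=species, site=site, year=year, age=AGE_JUVENILE)
            )
        return rows

    def test_too_few_juveniles_drops_species_only(self):
        rows = self._species_counts_table(5, 1, species="SP1")
        rows += self._species_counts_table(10, 10, species="SP2")
        table = make_table(rows)
        out = select_species_site_years(table)
        assert "SP1" not in set(out.df["species"])
        assert out.df[out.df["species"] == "SP2"]["ring_id"].nunique() == 20

    def test_exactly_two_and_two_retained(self):
        table = make_table(self._species_counts_table(2, 2))
        out = select_species_site_years(table)
        assert len(out.df) == 4

    def test_mean_individuals_threshold_boundary(self):
        rows = []
        for year, n in ((2000, 60), (2001, 40), (2002, 50)):
            for i in range(n):
                rows.append(capture_row(f"y{year}i{i}", year=year))
        table = make_table(rows)
        assert select_species(table) == [("SC", "SP")]  # mean exactly 50

    def test_mean_just_below_threshold_excluded(self):
        rows = []
        for year, n in ((2000, 50), (2001, 49)):
            for i in range(n):
                rows.append(capture_row(f"y{year}i{i}", year=year))
        table = make_table(rows)
        report = SelectionReport()
        assert select_species(table, report=report) == []
        assert any("49.50" in e["rule"] for e in report.entries)

    def test_relaxed_threshold_retains(self):
        rows = []
        for year, n in ((2000, 40), (2001, 40)):
            for i in range(n):
                rows.append(capture_row(f"y{year}i{i}", year=year))
        table = make_table(rows)
        relaxed = SelectionCriteria(min_mean_individuals_per_year=30)
        assert select_species(table, relaxed) == [("SC", "SP")]

    def test_filtering_is_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        rows = []
        for year in range(2000, 2004):
            for sp in ("A", "B", "C"):
                for i in range(int(rng.integers(5, 60))):
                    rows.append(capture_row(f"{sp}{year}i{i}", species=sp, year=year))
        table = make_table(rows)
        previous = None
        for threshold in (60, 40, 20, 5):
            kept = set(select_species(table, SelectionCriteria(min_mean_individuals_per_year=threshold)))
            if previous is not None:
                assert previous <= kept
            previous = kept


class TestBuildHistories:
    def _base_rows(self):
        rows = []
        for year in (2004, 2005, 2006):
            rows.append(capture_row(f"pad{year}", year=year, visit=1))
        return rows

    def test_within_year_captures_collapse(self):
        rows = self._base_rows()
        rows += [
            capture_row("A", year=2005, visit=3),
            capture_row("A", year=2005, visit=7),
        ]
        hist = build_histories(make_table(rows), "SP", "SC")
        i = hist.ring_ids.index("A")
        assert hist.detections[i].sum() == 1
        assert hist.years[hist.first[i]] == 2005

    def test_juvenile_year_excluded_from_history(self):
        rows = self._base_rows()
        rows += [
            capture_row("B", year=2004, age=AGE_JUVENILE),
            capture_row("B", year=2005),
        ]
        hist = build_histories(make_table(rows), "SP", "SC")
        i = hist.ring_ids.index("B")
        assert hist.years[hist.first[i]] == 2005
        assert hist.detections[i, hist.years.tolist().index(2004)] == 0

    def test_multi_site_assigned_to_first_and_flagged(self):
        rows = self._base_rows()
        rows += [
            capture_row("C", site="X", year=2004),
            capture_row("C", site="Y", year=2006),
        ]
        hist = build_histories(make_table(rows), "SP", "SC")
        i = hist.ring_ids.index("C")
        assert hist.site_codes[hist.site_index[i]] == "X"
        assert hist.multi_site[i]

    def test_too_few_years_raises(self):
        rows = [capture_row("A", year=2004), capture_row("B", year=2005)]
        with pytest.raises(DataError, match="3"):
            build_histories(make_table(rows), "SP", "SC")

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        rows = self._base_rows()
        rows += [
            capture_row("A", year=2004),
            capture_row("A", year=2006),
            capture_row("B", site="S2", year=2005),
        ]
        h1 = build_histories(make_table(rows), "SP", "SC")
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        h2 = build_histories(make_table(shuffled), "SP", "SC")
        assert h1.ring_ids == h2.ring_ids
        np.testing.assert_array_equal(h1.detections, h2.detections)
        np.testing.assert_array_equal(h1.site_index, h2.site_index)
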