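"""Report cleaning: dedup rule, target-case extraction, dates, SOC rollup."""

import datetime

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal import faers_io


def _demo(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid"])


class TestDeduplicate:
    def test_keeps_highest_primaryid(self):
        demo = _demo([("1001", "100"), ("1002", "100")])
        out, removed = faers_io.deduplicate(demo)
        assert list(out["primaryid"]) == ["1002"]
        assert removed == 1

    def test_deleted_case_fully_removed(self):
        demo = _demo([("1001", "100"), ("1002", "100"), ("2001", "200")])
        out, removed = faers_io.deduplicate(demo, deleted_caseids=["100"])
        assert list(out["caseid"]) == ["200"]
        assert removed == 2

    def test_idempotent_on_unique_input(self):
        demo = _demo([("1", "10"), ("2", "20"), ("3", "30")])
        once, removed = faers_io.deduplicate(demo)
        twice, removed2 = faers_io.deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)
        assert removed == removed2 == 0

    def test_tie_keeps_first_row_in_file_order(self):
        demo = pd.DataFrame(
            [("1001", "100", "first"), ("1001", "100", "second")],
            columns=["primaryid", "caseid", "marker"],
        )
        out, _ = faers_io.deduplicate(demo)
        assert list(out["marker"]) == ["first"]

    def test_non_numeric_primaryid_rejected(self):
        with pytest.raises(ValueError, match="non-numeric"):
            faers_io.deduplicate(_demo([("abc", "100")]))

    @given(st.lists(st.tuples(st.integers(1, 50), st.integers(1, 10)), min_size=1, max_size=40))
    def test_never_grows_and_output_caseids_subset(self, pairs):
        demo = _demo([(str(p), str(c)) for p, c in pairs])
        out, removed = faers_io.deduplicate(demo)
        assert len(out) <= len(demo)
        assert removed == len(demo) - len(out)
        assert set(out["caseid"]) <= set(demo["caseid"])
        assert out["caseid"].is_unique


class TestExtractTargetCases:
    @pytest.fixture()
    def drug(self):
        return pd.DataFrame({
            "caseid": ["1", "2", "3", "4"],
            "role_cod": ["PS", "PS", "C", "PS"],
            "drugname": ["RUBRACA", "  rucaparib  ", "rucaparib", "ASPIRIN"],
            "prod_ai": ["RUCAPARIB", "", "RUCAPARIB", "ACETYLSALICYLIC ACID"],
        })

    def test_matches_either_name_column_case_insensitively(self, drug):
        assert faers_io.extract_target_cases(drug, ["rucaparib", "rubraca"]) == {"1", "2"}

    def test_role_filter_excludes_concomitant(self, drug):
        assert "3" not in faers_io.extract_target_cases(drug, ["rucaparib"])
        assert faers_io.extract_target_cases(drug, ["rucaparib"], role="C") == {"3"}

    def test_substring_matches_brand_with_salt_text(self):
        drug = pd.DataFrame({
            "caseid": ["9"], "role_cod": ["PS"],
            "drugname": ["RUBRACA (RUCAPARIB CAMSYLATE)"], "prod_ai": [""],
        })
        assert faers_io.extract_target_cases(drug, ["rucaparib"]) == {"9"}

    def test_empty_synonyms_rejected(self, drug):
        with pytest.raises(ValueError):
            faers_io.extract_target_cases(drug, [])

    def test_invariant_to_case_and_whitespace_in_synonyms(self, drug):
        base = faers_io.extract_target_cases(drug, ["rucaparib"])
        assert faers_io.extract_target_cases(drug, ["  RucapariB  "]) == base


@pytest.mark.parametrize("text,expected_date,expected_precision", [
    ("20200115", datetime.date(2020, 1, 15), "day"),
    ("202001", None, "month"),
    ("2020", None, "year"),
    ("2017", None, "year"),
    ("", None, "missing"),
    (None, None, "missing"),
    ("202013", None, "invalid"),   # month 13
    ("20200230", None, "invalid"),  # Feb 30
    ("2020-1-5", None, "invalid"),
    ("123", None, "invalid"),
])
def test_parse_faers_date(text, expected_date, expected_precision):
    date, precision = faers_io.parse_faers_date(text)
    assert date == expected_date
    assert precision == expected_precision


class TestMapPtToSoc:
    @pytest.fixture()
    def dictionary(self):
        return pd.DataFrame({
            "pt": ["Nausea", "Oedema", "Oedema"],
            "soc": ["GI", "Cardiac", "Vascular"],
            "is_primary": [True, True, False],
        })

    def test_single_soc_pt_one_row_either_policy(self, dictionary):
        events = pd.DataFrame({"caseid": ["1"], "pt": ["Nausea"]})
        for policy in ("primary", "all"):
            out = faers_io.map_pt_to_soc(events, dictionary, policy=policy)
            assert len(out) == 1 and out.loc[0, "soc"] == "GI"

    def test_multi_soc_pt_policies_differ(self, dictionary):
        events = pd.DataFrame({"caseid": ["1"], "pt": ["Oedema"]})
        assert len(faers_io.map_pt_to_soc(events, dictionary, policy="all")) == 2
        primary = faers_io.map_pt_to_soc(events, dictionary, policy="primary")
        assert list(primary["soc"]) == ["Cardiac"]

    def test_unmapped_pt_flagged_not_dropped(self, dictionary):
        events = pd.DataFrame({"caseid": ["1", "1"], "pt": ["Nausea", "Mystery term"]})
        out = faers_io.map_pt_to_soc(events, dictionary)
        assert set(out["soc"]) == {"GI", "UNMAPPED"}
        assert out.attrs["n_unmapped_pts"] == 1

    def test_conflicting_primary_flags_rejected(self):
        bad = pd.DataFrame({
            "pt": ["X", "X"], "soc": ["A", "B"], "is_primary": [True, True],
        })
        events = pd.DataFrame({"caseid": ["1"], "pt": ["X"]})
        with pytest.raises(ValueError, match="primary"):
            faers_io.map_pt_to_soc(events, bad)

    def test_duplicate_reac_rows_counted_once(self, dictionary):
        events = pd.DataFrame({"caseid": ["1", "1", "1"], "pt": ["Nausea"] * 3})
        assert len(faers_io.map_pt_to_soc(events, dictionary)) == 1

    def test_policy_all_rowcount_matches_naive_join(self, small_cohort):
        _, cohort = small_cohort
        dic = cohort.dictionary
        events = cohort.tables["reac"]
        out = faers_io.map_pt_to_soc(events, dic, policy="all")
        pairs = events[["caseid", "pt"]].drop_duplicates()
        links_per_pt = dic.drop_duplicates(["pt", "soc"]).groupby("pt").size()
        expected = int(pairs["pt"].map(links_per_pt).fillna(1).sum())  # unmapped → 1 row
        assert len(out) == expected


class TestReadTables:
    def test_missing_table_error_names_file(self, cohort_dir, tmp_path):
        import shutil

        partial = tmp_path / "partial"
        shutil.copytree(cohort_dir, partial)
        for p in partial.glob("REAC*.txt"):
            p.unlink()
        with pytest.raises(FileNotFoundError, match="REAC"):
            faers_io.read_tables(partial)

    def test_header_only_table_gives_zero_rows(self, tmp_path):
        for prefix in faers_io.TABLE_PREFIXES.values():
            (tmp_path / f"{prefix}22Q2.txt").write_text("primaryid$caseid\n")
        tables = faers_io.read_tables(tmp_path)
        assert all(len(df) == 0 for df in tables.values())

    def test_ids_read_as_text(self, cohort_dir):
        tables = faers_io.read_tables(cohort_dir)
        assert tables["demo"]["primaryid"].map(type).eq(str).all()


class TestBuildCases:
    def test_serious_iff_outcomes_nonempty(self, small_cohort):
        _, cohort = small_cohort
        cases = faers_io.build_cases(cohort.tables, cohort.deleted_caseids)
        assert (cases["serious"] == cases["outcomes"].map(bool)).all()
        assert cases["caseid"].is_unique

    def test_age_unit_harmonisation(self):
        assert faers_io._age_to_years("7", "DEC") == pytest.approx(70.0)
        assert faers_io._age_to_years("24", "MON") == pytest.approx(2.0)
        assert faers_io._age_to_years("365.25", "DY") == pytest.approx(1.0)
        assert pd.isna(faers_io._age_to_years("5", "??"))
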