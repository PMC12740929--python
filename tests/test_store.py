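"""Ingestion, deduplication, name normalisation and cohort selection."""

import pytest

from faersig import (
    apply_completeness_filter,
    deduplicate,
    normalize_drug_name,
    read_quarter,
    select_primary_suspect,
)
from faersig.store import load_synonym_table

from conftest import demo_row, drug_row, load_quarter, write_quarter


class TestReadQuarter:
    def test_three_case_quarter_loads_all_records(self, tmp_path):
        paths = write_quarter(
            tmp_path,
            demo=[demo_row("1"), demo_row("2"), demo_row("3")],
            drug=[drug_row("1"), drug_row("2"), drug_row("3", name="ASPIRIN")],
            reac=[["1", "Nausea"], ["1", "Headache"], ["2", "Diarrhoea"], ["3", "Nausea"]],
        )
        store = load_quarter(paths)
        assert len(store) == 3
        assert len(store.drugs) == 3
        assert len(store.reactions) == 4

    def test_empty_reaction_file_yields_empty_reactions(self, tmp_path):
        paths = write_quarter(tmp_path, demo=[demo_row("1")], drug=[drug_row("1")], reac=[])
        store = load_quarter(paths)
        assert len(store.reactions) == 0
        assert len(store) == 1

    def test_malformed_row_is_logged_not_fatal(self, tmp_path):
        paths = write_quarter(tmp_path, demo=[demo_row("1")], drug=[drug_row("1")], reac=[["1", "Nausea"]])
        with open(paths["REAC"], "a") as fh:
            fh.write("only_one_field\n")
        store = load_quarter(paths)
        assert len(store.reactions) == 1
        assert any("1 malformed" in line for line in store.provenance)

    def test_missing_file_is_fatal_and_names_it(self, tmp_path):
        paths = write_quarter(tmp_path, demo=[demo_row("1")], drug=[drug_row("1")], reac=[])
        with pytest.raises(FileNotFoundError, match="DRUG"):
            read_quarter(paths["DEMO"], tmp_path / "nope.csv", paths["REAC"], paths["THER"])

    def test_unknown_dialect_is_fatal(self, tmp_path):
        paths = write_quarter(tmp_path, demo=[demo_row("1")], drug=[drug_row("1")], reac=[])
        with pytest.raises(ValueError, match="dialect"):
            read_quarter(paths["DEMO"], paths["DRUG"], paths["REAC"], paths["THER"], "tsv")

    def test_faers_ascii_and_simple_csv_parse_identically(self, tmp_path):
        rows = dict(
            demo=[demo_row("1", event="20240105", outc="DE,HO"), demo_row("2", sex="F", age="")],
            drug=[drug_row("1"), drug_row("2", role="C", name="DALIRESP")],
            reac=[["1", "Nausea"], ["2", "Insomnia"]],
            ther=[["1", "1", "20240101"]],
        )
        (tmp_path / "a").mkdir()
        (tmp_path / "b").mkdir()
        a = load_quarter(write_quarter(tmp_path / "a", **rows), "simple-csv")
        b_paths = write_quarter(tmp_path / "b", **rows, dialect="faers-ascii")
        b = read_quarter(b_paths["DEMO"], b_paths["DRUG"], b_paths["REAC"], b_paths["THER"], "faers-ascii")
        for attr in ("demo", "drugs", "reactions"):
            assert getattr(a, attr).equals(getattr(b, attr))

    def test_partial_dates_kept_with_reduced_precision(self, tmp_path):
        paths = write_quarter(
            tmp_path,
            demo=[demo_row("1", event="202403"), demo_row("2", event="2024"), demo_row("3", event="bogus")],
            drug=[drug_row("1"), drug_row("2"), drug_row("3")],
            reac=[],
        )
        demo = load_quarter(paths).demo.set_index("case_id")
        assert demo.loc["1", "event_precision"] == "month"
        assert demo.loc["2", "event_precision"] == "year"
        assert demo.loc["3", "event_precision"] == ""
        assert demo.loc["3", "event_date"] is not None  # NaT, not a crash


def _versioned_store(tmp_path, versions):
    """versions: list of (caseid, version, fda_dt) DEMO rows for one drug/reaction set."""
    demo = [demo_row(cid, version=v, fda=fda) for cid, v, fda in versions]
    cases = {cid for cid, _, _ in versions}
    return load_quarter(write_quarter(
        tmp_path, demo=demo,
        drug=[drug_row(cid) for cid in sorted(cases)],
        reac=[[cid, "Nausea"] for cid in sorted(cases)],
    ))


class TestDeduplicate:
    def test_latest_fda_date_wins(self, tmp_path):
        store = _versioned_store(tmp_path, [("123", "1", "20240101"), ("123", "2", "20240301")])
        dedup = deduplicate(store)
        assert len(dedup) == 1
        assert dedup.demo.iloc[0]["report_version"] == 2

    def test_equal_fda_dates_tie_break_on_version(self, tmp_path):
        store = _versioned_store(tmp_path, [("123", "3", "20240101"), ("123", "1", "20240101")])
        assert deduplicate(store).demo.iloc[0]["report_version"] == 3

    def test_absent_fda_date_sorts_lowest(self, tmp_path):
        store = _versioned_store(tmp_path, [("123", "5", ""), ("123", "1", "20200101")])
        assert deduplicate(store).demo.iloc[0]["report_version"] == 1

    def test_single_version_store_unchanged(self, tmp_path):
        store = _versioned_store(tmp_path, [("1", "1", "20240101"), ("2", "1", "20240201")])
        dedup = deduplicate(store)
        assert dedup.demo[["case_id", "report_version"]].equals(store.demo[["case_id", "report_version"]])

    def test_idempotent_and_shrinking(self, synth_files):
        store = load_quarter(synth_files)
        once = deduplicate(store)
        twice = deduplicate(once)
        assert once.demo.equals(twice.demo)
        assert len(once) <= len(store)
        assert set(once.demo["case_id"]) <= set(store.demo["case_id"])
        assert once.demo["case_id"].is_unique


class TestNormalizeDrugName:
    @pytest.mark.parametrize(
        "verbatim, expected",
        [
            ("DALIRESP", "roflumilast"),
            ("  Roflumilast ", "roflumilast"),
            ("Daxas", "roflumilast"),
            ("aspirin", "aspirin"),
            ("ASPIRIN  (oral)", "aspirin oral"),
        ],
    )
    def test_examples(self, verbatim, expected):
        assert normalize_drug_name(verbatim) == expected

    def test_user_synonym_table_extends_defaults(self, tmp_path):
        path = tmp_path / "syn.csv"
        path.write_text("verbatim,canonical\nAcme Cough Syrup,dextromethorphan\n")
        table = load_synonym_table(path)
        assert normalize_drug_name("ACME COUGH  SYRUP", table) == "dextromethorphan"
        assert normalize_drug_name("Daliresp", table) == "roflumilast"


class TestSelectPrimarySuspect:
    def test_ps_role_included_concomitant_excluded(self, tmp_path):
        paths = write_quarter(
            tmp_path,
            demo=[demo_row("1"), demo_row("2")],
            drug=[drug_row("1", role="PS"), drug_row("2", role="C")],
            reac=[["1", "Nausea"], ["2", "Nausea"]],
        )
        store = load_quarter(paths)
        assert select_primary_suspect(store, "roflumilast") == {"1"}

    def test_empty_store_yields_empty_set(self, tmp_path):
        store = load_quarter(write_quarter(tmp_path, demo=[], drug=[], reac=[]))
        assert select_primary_suspect(store, "roflumilast") == set()

    def test_selection_is_subset_of_store(self, synth_store):
        ids = select_primary_suspect(synth_store, "roflumilast")
        assert ids <= synth_store.case_ids
        assert ids  # the generator injects target cases


class TestCompletenessFilter:
    def test_case_without_reactions_removed(self, tmp_path):
        paths = write_quarter(
            tmp_path,
            demo=[demo_row("1"), demo_row("2")],
            drug=[drug_row("1"), drug_row("2")],
            reac=[["1", "Nausea"]],
        )
        filtered = apply_completeness_filter(load_quarter(paths))
        assert filtered.case_ids == {"1"}
        assert any("completeness" in line for line in filtered.provenance)

    def test_all_incomplete_gives_empty_store(self, tmp_path):
        paths = write_quarter(tmp_path, demo=[demo_row("1")], drug=[drug_row("1")], reac=[])
        filtered = apply_completeness_filter(load_quarter(paths))
        assert len(filtered) == 0

    def test_fully_populated_case_retained(self, tmp_path):
        paths = write_quarter(tmp_path, demo=[demo_row("1")], drug=[drug_row("1")], reac=[["1", "Nausea"]])
        assert apply_completeness_filter(load_quarter(paths)).case_ids == {"1"}


def test_generator_round_trip_counts(synth_dataset, synth_files):
    """read_quarter loads exactly the rows the generator emitted."""
    store = load_quarter(synth_files)
    assert len(store.demo) == len(synth_dataset.demo)
    assert len(store.drugs) == len(synth_dataset.drug)
    assert len(store.reactions) == len(synth_dataset.reac)
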