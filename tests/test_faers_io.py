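"""Reading and writing the dollar-delimited quarterly dialect and the
canonical store form."""

import warnings

import pandas as pd
import pytest

from pvsignal.faers_io import (normalize_drug_name, read_faers_tables,
                               read_flat_csv, write_faers_dialect, write_flat_csv)
from pvsignal.records import ReportStore
from pvsignal.synth import SyntheticConfig, generate

from conftest import TOY_VOCAB


def _write(path, header, rows):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def dialect_dir(tmp_path):
    _write(tmp_path / "DEMO.txt",
           "primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$occp_cod$occr_country",
           ["1$c1$20200101$20200110$M$65$YR$70$KG$MD$US",
            "2$c2$20200201$$F$6.5$DEC$154$LBS$CN$JP",
            "3$c3$20200301$20200302$M$540$MON$$$PH$FR",
            "4$c4$20200401$$F$200$YR$$$MD$US",   # age out of range -> missing
            "5$c5$20200501$$M$30$YR$$$MD$US"])   # no REAC rows -> dropped
    _write(tmp_path / "DRUG.txt", "primaryid$drug_seq$drugname$role_cod",
           ["1$1$STIVARGA$PS", "1$2$aspirin$C", "2$1$Regorafenib$PS",
            "3$1$drugA$PS", "4$1$drugA$PS", "5$1$drugA$PS",
            "9$1$ghost$PS"])  # orphan
    _write(tmp_path / "REAC.txt", "primaryid$pt",
           ["1$nausea", "1$headache", "1$headache",  # duplicate PT within report
            "2$rash", "3$headache", "4$nausea"])
    _write(tmp_path / "THER.txt", "primaryid$dsg_drug_seq$start_dt",
           ["1$1$20200105", "2$1$bad-date"])
    _write(tmp_path / "OUTC.txt", "primaryid$outc_cod", ["1$HO", "1$DE", "2$CA"])
    _write(tmp_path / "INDI.txt", "primaryid$indi_drug_seq$indi_pt",
           ["1$1$colorectal cancer"])
    return tmp_path


def _paths(d):
    return {k: d / f"{k.upper()}.txt" for k in ("demo", "drug", "reac", "ther", "outc", "indi")}


class TestReadFaersTables:
    def test_identity_join_builds_one_record_per_demo_row(self, dialect_dir):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            store = read_faers_tables(_paths(dialect_dir), TOY_VOCAB)
        # report 5 has no reactions and is dropped
        assert sorted(store.report_ids()) == ["1", "2", "3", "4"]
        counts = store.reactions.groupby("report_id").size()
        assert (counts >= 1).all()
        assert any("without reaction rows" in m for m in store.provenance["log"])

    def test_age_and_weight_unit_conversion(self, dialect_dir):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            store = read_faers_tables(_paths(dialect_dir), TOY_VOCAB)
        r = store.reports.set_index("report_id")
        assert r.loc["2", "age_years"] == pytest.approx(65.0)      # 6.5 decades
        assert r.loc["3", "age_years"] == pytest.approx(45.0)      # 540 months
        assert r.loc["2", "weight_kg"] == pytest.approx(154 * 0.45359237)
        assert pd.isna(r.loc["4", "age_years"])                    # 200 yr implausible

    def test_orphan_child_rows_skipped_with_warning(self, dialect_dir):
        with pytest.warns(UserWarning, match="unknown primaryid"):
            store = read_faers_tables(_paths(dialect_dir), TOY_VOCAB)
        assert "9" not in set(store.drugs["report_id"])

    def test_duplicate_pt_within_report_collapsed(self, dialect_dir):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            store = read_faers_tables(_paths(dialect_dir), TOY_VOCAB)
        r1 = store.reactions[store.reactions["report_id"] == "1"]
        assert sorted(r1["pt"]) == ["headache", "nausea"]

    def test_unparseable_dates_become_missing_and_logged(self, dialect_dir):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            store = read_faers_tables(_paths(dialect_dir), TOY_VOCAB)
        r = store.reports.set_index("report_id")
        assert pd.isna(r.loc["2", "therapy_start"])
        assert any("unparseable" in m for m in store.provenance["log"])

    def test_unknown_outcome_codes_fold_into_other(self, dialect_dir):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            store = read_faers_tables(_paths(dialect_dir), TOY_VOCAB)
        o2 = store.outcomes[store.outcomes["report_id"] == "2"]
        assert list(o2["outcome"]) == ["OT"]

    def test_missing_mandatory_column_is_hard_error(self, tmp_path, dialect_dir):
        bad = _write(tmp_path / "DEMO_BAD.txt", "primaryid$caseid",
                     ["1$c1"])
        paths = _paths(dialect_dir)
        paths["demo"] = bad
        with pytest.raises(ValueError, match="fda_dt"):
            read_faers_tables(paths, TOY_VOCAB)


class TestRoundTrips:
    def test_dialect_write_read_preserves_key_fields(self, tmp_path):
        cfg = SyntheticConfig(n_reports=300, n_events=20, seed=3, duplicate_rate=0.0)
        store, _ = generate(cfg)
        paths = write_faers_dialect(store, tmp_path)
        back = read_faers_tables(paths, store.vocabulary)
        assert back.n_reports == store.n_reports
        merged = store.reports.merge(back.reports, on="report_id", suffixes=("_a", "_b"))
        assert (merged["sex_a"].fillna("") == merged["sex_b"].fillna("")).all()
        assert merged["age_years_b"].sub(merged["age_years_a"]).abs().max() < 1e-6
        a = store.reactions.sort_values(["report_id", "pt"]).reset_index(drop=True)
        b = back.reactions.sort_values(["report_id", "pt"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        # therapy_start and onset survive where present
        assert (merged["therapy_start_a"].isna() == merged["therapy_start_b"].isna()).all()

    def test_demo_row_count_matches_store(self, tmp_path):
        cfg = SyntheticConfig(n_reports=100, n_events=10, seed=4, duplicate_rate=0.0)
        store, _ = generate(cfg)
        paths = write_faers_dialect(store, tmp_path)
        demo_lines = open(paths["demo"]).read().strip().splitlines()
        assert len(demo_lines) - 1 == 100

    def test_canonical_store_round_trip(self, tmp_path, toy_store):
        toy_store.write(tmp_path / "store")
        back = ReportStore.read(tmp_path / "store")
        assert sorted(back.report_ids()) == sorted(toy_store.report_ids())
        assert back.vocabulary.pt_to_soc == toy_store.vocabulary.pt_to_soc
        pd.testing.assert_frame_equal(
            back.reactions.sort_values(["report_id", "pt"]).reset_index(drop=True),
            toy_store.reactions.sort_values(["report_id", "pt"]).reset_index(drop=True))

    def test_flat_csv_round_trip(self, tmp_path, toy_store):
        path = tmp_path / "flat.csv"
        write_flat_csv(toy_store, path)
        back = read_flat_csv(path, toy_store.vocabulary)
        assert back.n_reports == toy_store.n_reports
        assert set(map(tuple, back.reactions.values)) == set(map(tuple, toy_store.reactions.values))


def test_normalize_drug_name_strips_case_space_punctuation():
    assert normalize_drug_name(" STIVARGA  ") == "stivarga"
    assert normalize_drug_name("Drug-A (tablet)") == "drugatablet"
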