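import numpy as np
import pandas as pd
import pytest

from pvsignal.records import ReportRecord, ReportStore, Vocabulary
from pvsignal.synth import SyntheticConfig, generate

TOY_VOCAB = Vocabulary(
    {"headache": "nervous", "nausea": "gastrointestinal", "rash": "skin",
     "hepatic_failure": "hepatobiliary"},
    dme_terms=frozenset({"hepatic_failure"}),
    ime_terms=frozenset({"rash"}),
)


def _record(rid, drug="X", role="PS", reactions=("headache",), **kw):
    defaults = dict(case_id=f"case-{rid}", receipt_date=pd.Timestamp("2020-01-01"),
                    drugs=[(drug, role)], reactions=list(reactions), sex="male",
                    age_years=60.0, outcomes=set())
    defaults.update(kw)
    return ReportRecord(report_id=rid, **defaults)


@pytest.fixture
def toy_store():
    """Four reports whose (report, event) pairs are enumerable by hand.

    Pairs: r1 (X,headache)(X,nausea); r2 (X,headache); r3 (Y,nausea)(Y,rash);
    r4 (Z,rash)(Z,headache).  Total 7 pairs.
    """
    records = [
        _record("r1", "X", reactions=["headache", "nausea"]),
        _record("r2", "X", reactions=["headache"]),
        _record("r3", "Y", reactions=["nausea", "rash"]),
        _record("r4", "Z", reactions=["rash", "headache"]),
    ]
    return ReportStore.from_records(records, TOY_VOCAB)


@pytest.fixture(scope="session")
def small_universe():
    """A modest seeded synthetic universe shared by read-only tests."""
    cfg = SyntheticConfig(n_reports=8000, n_events=60, seed=11)
    store, truth = generate(cfg)
    return store, truth


def make_record(rid, **kw):
    return _record(rid, **kw)


def store_for_table(a, b, c, d, drug="X", other="Y", event="headache",
                    other_event="nausea"):
    """A store whose (drug, event) 2x2 table is exactly (a, b, c, d),
    built vectorized so large cells stay cheap."""
    n = a + b + c + d
    rid = np.array([f"r{i}" for i in range(n)], dtype=object)
    reports = pd.DataFrame({
        "report_id": rid, "case_id": rid,
        "receipt_date": pd.Timestamp("2020-01-01"), "sex": "male",
        "age_years": 60.0, "weight_kg": np.nan, "reporter": None,
        "country": None, "therapy_start": pd.NaT, "event_onset": pd.NaT,
    })
    drugs = pd.DataFrame({"report_id": rid,
                          "drug": np.repeat([drug, drug, other, other], [a, b, c, d]),
                          "role": "PS"})
    reactions = pd.DataFrame({"report_id": rid,
                              "pt": np.repeat([event, other_event] * 2, [a, b, c, d])})
    empty_o = pd.DataFrame(columns=["report_id", "outcome"])
    empty_i = pd.DataFrame(columns=["report_id", "pt"])
    return ReportStore(reports, drugs, reactions, empty_o, empty_i, TOY_VOCAB)
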