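"""2x2 contingency tables for drug-event disproportionality.

The counting unit is the (report, event) pair: a report listing k distinct
preferred terms contributes k pairs to the database universe.  For a target
drug D and event e,

    a = pairs where the report has D as primary suspect and the event is e
    b = primary-suspect-D pairs with any other event
    c = pairs with event e under any other drug
    d = everything else

At SOC level, each report's PTs are first mapped to their system organ
class and de-duplicated within the report before pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ReportStore


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.n <= 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """E = (a+b)(a+c)/n, the count expected under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


def _event_pairs(store: ReportStore, level: str) -> pd.DataFrame:
    """(report_id, event) pairs at PT or SOC level, distinct within report."""
    if level == "PT":
        pairs = store.reactions[["report_id", "pt"]].rename(columns={"pt": "event"})
    elif level == "SOC":
        pairs = store.reactions.assign(
            event=store.reactions["pt"].map(store.vocabulary.soc_of))[["report_id", "event"]]
    else:
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    return pairs.drop_duplicates()


def _drug_flag(store: ReportStore, drug: str) -> pd.Series:
    """Per report_id: does the report carry `drug` as primary suspect?"""
    ps = store.drugs[(store.drugs["role"] == "PS") & (store.drugs["drug"] == drug)]
    return store.reports["report_id"].isin(set(ps["report_id"]))


def pair_counts(store: ReportStore, drug: str, level: str = "PT") -> pd.DataFrame:
    """Per-event a/b/c/d for one drug against the whole-store background.

    Returns a DataFrame indexed by event with integer columns a, b, c, d —
    one row per event occurring anywhere in the store.
    """
    pairs = _event_pairs(store, level)
    flag = _drug_flag(store, drug)
    drug_ids = set(store.reports.loc[flag.values, "report_id"])
    with_drug = pairs["report_id"].isin(drug_ids)

    a = pairs.loc[with_drug, "event"].value_counts()
    ec = pairs.loc[~with_drug, "event"].value_counts()
    events = pairs["event"].unique()
    out = pd.DataFrame(index=pd.Index(sorted(events), name="event"))
    out["a"] = a.reindex(out.index).fillna(0).astype(int)
    out["c"] = ec.reindex(out.index).fillna(0).astype(int)
    n_drug_pairs = int(with_drug.sum())
    n_pairs = len(pairs)
    out["b"] = n_drug_pairs - out["a"]
    out["d"] = n_pairs - n_drug_pairs - out["c"]
    return out


def build_table(store: ReportStore, drug: str, event: str, level: str = "PT") -> ContingencyTable:
    """The 2x2 table for one (drug, event) pair.

    Raises ``KeyError`` if the event never occurs in the store (at the
    requested level); an absent drug simply yields a = b = 0.
    """
    counts = pair_counts(store, drug, level)
    if event not in counts.index:
        raise KeyError(f"event {event!r} does not occur in the store at level {level}")
    row = counts.loc[event]
    return ContingencyTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))


def all_pair_counts(store: ReportStore, level: str = "PT") -> pd.DataFrame:
    """a and E for every (primary-suspect drug, event) combination.

    This is the screening universe used to fit the empirical-Bayes prior:
    one row per (drug, event) with observed count ``a`` and expected count
    ``E`` under row/column independence of the pair universe.
    """
    pairs = _event_pairs(store, level)
    ps = store.ps_drug()
    pairs = pairs.assign(drug=pairs["report_id"].map(ps)).dropna(subset=["drug"])
    ct = pairs.groupby(["drug", "event"]).size().rename("a").reset_index()
    drug_tot = ct.groupby("drug")["a"].sum()
    event_tot = ct.groupby("event")["a"].sum()
    n = ct["a"].sum()
    ct["E"] = ct["drug"].map(drug_tot) * ct["event"].map(event_tot) / n
    return ct
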