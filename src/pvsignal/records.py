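"""Core data model for collections of spontaneous adverse-event reports.

A :class:`ReportStore` holds a deduplicatable set of reports in normalized
pandas tables (one row per report, plus child tables for drugs, reactions,
outcomes and indications), together with the controlled vocabulary used to
map preferred terms (PTs) to system organ classes (SOCs) and to look up
serious-event designations (DME/IME lists).

The record-level view (:class:`ReportRecord`) exists for construction,
round-tripping and tests; all heavy computation works on the tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

DRUG_ROLES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "DS", "HO", "OT")
SEXES = ("male", "female")

#: plausibility bounds applied at ingest; values outside become missing
AGE_BOUNDS = (0.0, 120.0)
WEIGHT_BOUNDS = (1.0, 500.0)


@dataclass(frozen=True)
class Vocabulary:
    """PT -> SOC mapping plus the serious-event term lists.

    ``dme_terms`` (designated medical events: rare, serious, high drug
    causality) and ``ime_terms`` (important medical events) are independent
    sets; a PT may appear in either, both, or neither.
    """

    pt_to_soc: dict
    dme_terms: frozenset = frozenset()
    ime_terms: frozenset = frozenset()

    def soc_of(self, pt: str) -> str:
        try:
            return self.pt_to_soc[pt]
        except KeyError:
            raise KeyError(f"PT {pt!r} has no SOC assignment in the vocabulary") from None

    @staticmethod
    def from_frames(pt_soc: pd.DataFrame, dme: Sequence[str] = (), ime: Sequence[str] = ()) -> "Vocabulary":
        mapping = dict(zip(pt_soc["pt"], pt_soc["soc"]))
        return Vocabulary(mapping, frozenset(dme), frozenset(ime))


@dataclass
class ReportRecord:
    """One spontaneous report after parsing and normalization."""

    report_id: str
    case_id: Optional[str] = None
    receipt_date: Optional[pd.Timestamp] = None
    drugs: list = field(default_factory=list)  # [(normalized name, role)]
    reactions: list = field(default_factory=list)  # PT strings
    sex: Optional[str] = None  # 'male' / 'female' / None
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    outcomes: set = field(default_factory=set)  # subset of OUTCOME_CODES
    reporter: Optional[str] = None
    country: Optional[str] = None
    indication_pts: list = field(default_factory=list)
    therapy_start: Optional[pd.Timestamp] = None
    event_onset: Optional[pd.Timestamp] = None

    def validate(self) -> None:
        for _, role in self.drugs:
            if role not in DRUG_ROLES:
                raise ValueError(f"report {self.report_id}: unknown drug role {role!r}")
        for o in self.outcomes:
            if o not in OUTCOME_CODES:
                raise ValueError(f"report {self.report_id}: unknown outcome code {o!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"report {self.report_id}: unknown sex {self.sex!r}")
        if not self.reactions:
            raise ValueError(f"report {self.report_id}: no reactions after parsing")
        if self.age_years is not None and not (AGE_BOUNDS[0] <= self.age_years <= AGE_BOUNDS[1]):
            raise ValueError(f"report {self.report_id}: age {self.age_years} out of bounds")
        if self.weight_kg is not None and not (WEIGHT_BOUNDS[0] <= self.weight_kg <= WEIGHT_BOUNDS[1]):
            raise ValueError(f"report {self.report_id}: weight {self.weight_kg} out of bounds")


REPORT_COLUMNS = [
    "report_id", "case_id", "receipt_date", "sex", "age_years", "weight_kg",
    "reporter", "country", "therapy_start", "event_onset",
]


@dataclass
class ReportStore:
    """Normalized tables for a set of reports plus vocabulary and provenance.

    ``reports`` has one row per report (columns :data:`REPORT_COLUMNS`);
    ``drugs``/``reactions``/``outcomes``/``indications`` are child tables
    keyed on ``report_id``.  ``provenance`` is a free-form ingestion log
    (source files, row counts, deduplication counts).
    """

    reports: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    indications: pd.DataFrame
    vocabulary: Vocabulary
    provenance: dict = field(default_factory=dict)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def report_ids(self) -> pd.Series:
        return self.reports["report_id"]

    def ps_drug(self) -> pd.Series:
        """First primary-suspect drug name per report (index: report_id)."""
        ps = self.drugs[self.drugs["role"] == "PS"]
        return ps.groupby("report_id")["drug"].first()

    def log(self, message: str) -> None:
        self.provenance.setdefault("log", []).append(message)

    # -- record-level view -------------------------------------------------

    @staticmethod
    def from_records(records: Iterable[ReportRecord], vocabulary: Vocabulary,
                     provenance: Optional[dict] = None, validate: bool = True) -> "ReportStore":
        records = list(records)
        if validate:
            for r in records:
                r.validate()
        rep_rows, drug_rows, reac_rows, outc_rows, indi_rows = [], [], [], [], []
        for r in records:
            rep_rows.append((r.report_id, r.case_id, r.receipt_date, r.sex,
                             r.age_years, r.weight_kg, r.reporter, r.country,
                             r.therapy_start, r.event_onset))
            drug_rows.extend((r.report_id, name, role) for name, role in r.drugs)
            reac_rows.extend((r.report_id, pt) for pt in r.reactions)
            outc_rows.extend((r.report_id, o) for o in sorted(r.outcomes))
            indi_rows.extend((r.report_id, pt) for pt in r.indication_pts)
        reports = pd.DataFrame(rep_rows, columns=REPORT_COLUMNS)
        for col in ("receipt_date", "therapy_start", "event_onset"):
            reports[col] = pd.to_datetime(reports[col])
        return ReportStore(
            reports=reports,
            drugs=pd.DataFrame(drug_rows, columns=["report_id", "drug", "role"]),
            reactions=pd.DataFrame(reac_rows, columns=["report_id", "pt"]),
            outcomes=pd.DataFrame(outc_rows, columns=["report_id", "outcome"]),
            indications=pd.DataFrame(indi_rows, columns=["report_id", "pt"]),
            vocabulary=vocabulary,
            provenance=provenance or {},
        )

    def to_records(self) -> Iterator[ReportRecord]:
        drugs = {k: list(zip(g["drug"], g["role"])) for k, g in self.drugs.groupby("report_id")}
        reacs = {k: list(g["pt"]) for k, g in self.reactions.groupby("report_id")}
        outcs = {k: set(g["outcome"]) for k, g in self.outcomes.groupby("report_id")}
        indis = {k: list(g["pt"]) for k, g in self.indications.groupby("report_id")}

        def _none(x):
            return None if (x is None or (isinstance(x, float) and np.isnan(x)) or x is pd.NaT) else x

        for row in self.reports.itertuples(index=False):
            rid = row.report_id
            yield ReportRecord(
                report_id=rid,
                case_id=_none(row.case_id),
                receipt_date=_none(row.receipt_date),
                drugs=drugs.get(rid, []),
                reactions=reacs.get(rid, []),
                sex=_none(row.sex),
                age_years=_none(row.age_years),
                weight_kg=_none(row.weight_kg),
                outcomes=outcs.get(rid, set()),
                reporter=_none(row.reporter),
                country=_none(row.country),
                indication_pts=indis.get(rid, []),
                therapy_start=_none(row.therapy_start),
                event_onset=_none(row.event_onset),
            )

    # -- subsetting --------------------------------------------------------

    def subset(self, report_ids: pd.Series | Sequence[str]) -> "ReportStore":
        """New store restricted to the given report ids (order preserved)."""
        keep = set(report_ids)
        return ReportStore(
            reports=self.reports[self.reports["report_id"].isin(keep)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["report_id"].isin(keep)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["report_id"].isin(keep)].reset_index(drop=True),
            outcomes=self.outcomes[self.outcomes["report_id"].isin(keep)].reset_index(drop=True),
            indications=self.indications[self.indications["report_id"].isin(keep)].reset_index(drop=True),
            vocabulary=self.vocabulary,
            provenance=dict(self.provenance),
        )

    def with_provenance(self, **updates) -> "ReportStore":
        prov = dict(self.provenance)
        prov.update(updates)
        return replace(self, provenance=prov)

    # -- canonical on-disk form -------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        """Write the canonical CSV form plus a JSON provenance sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reports.to_csv(out / "reports.csv", index=False)
        self.drugs.to_csv(out / "drugs.csv", index=False)
        self.reactions.to_csv(out / "reactions.csv", index=False)
        self.outcomes.to_csv(out / "outcomes.csv", index=False)
        self.indications.to_csv(out / "indications.csv", index=False)
        vocab = {
            "pt_to_soc": self.vocabulary.pt_to_soc,
            "dme_terms": sorted(self.vocabulary.dme_terms),
            "ime_terms": sorted(self.vocabulary.ime_terms),
        }
        (out / "vocabulary.json").write_text(json.dumps(vocab, indent=1, sort_keys=True))
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1, default=str))

    @staticmethod
    def read(in_dir: str | Path) -> "ReportStore":
        src = Path(in_dir)
        reports = pd.read_csv(src / "reports.csv", dtype={"report_id": str, "case_id": str},
                              parse_dates=["receipt_date", "therapy_start", "event_onset"])
        def _child(name, cols):
            df = pd.read_csv(src / name, dtype={"report_id": str})
            return df if len(df) else pd.DataFrame(columns=cols)
        vocab = json.loads((src / "vocabulary.json").read_text())
        prov = json.loads((src / "provenance.json").read_text()) if (src / "provenance.json").exists() else {}
        return ReportStore(
            reports=reports,
            drugs=_child("drugs.csv", ["report_id", "drug", "role"]),
            reactions=_child("reactions.csv", ["report_id", "pt"]),
            outcomes=_child("outcomes.csv", ["report_id", "outcome"]),
            indications=_child("indications.csv", ["report_id", "pt"]),
            vocabulary=Vocabulary(vocab["pt_to_soc"], frozenset(vocab["dme_terms"]),
                                  frozenset(vocab["ime_terms"])),
            provenance=prov,
        )
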