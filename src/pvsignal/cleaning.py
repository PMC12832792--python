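"""Report deduplication and primary-suspect cohort selection.

Spontaneous-report databases accumulate follow-up versions of the same
case.  Deduplication keeps, within each group of reports describing the
same case, only the most recently received version, so an adverse-event
instance is counted once.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import pandas as pd

from .faers_io import normalize_drug_name
from .records import ReportStore


def _dedup_key(store: ReportStore) -> pd.Series:
    """Grouping key: the case identifier when present, otherwise the
    (event date, primary-suspect drug, sorted reaction list) triple."""
    r = store.reports
    ps = store.ps_drug()
    reac_key = store.reactions.sort_values(["report_id", "pt"]).groupby("report_id")["pt"].agg(
        lambda s: "|".join(s))
    fallback = (
        "surrogate:" + r["event_onset"].astype(str)
        + "/" + r["report_id"].map(ps).fillna("")
        + "/" + r["report_id"].map(reac_key).fillna("")
    )
    key = ("case:" + r["case_id"]).where(r["case_id"].notna(), fallback)
    return key


def deduplicate(store: ReportStore) -> ReportStore:
    """Keep one report per case: the greatest receipt date, ties broken by
    the lexicographically greatest report id.  Idempotent."""
    r = store.reports
    if len(r) == 0:
        return store.with_provenance(dedup={"before": 0, "after": 0, "removed": 0})
    key = _dedup_key(store)
    ranked = pd.DataFrame({
        "report_id": r["report_id"].values,
        "key": key.values,
        "receipt_date": r["receipt_date"].values,
    })
    ranked = ranked.sort_values(["key", "receipt_date", "report_id"],
                                na_position="first", kind="mergesort")
    survivors = ranked.groupby("key", sort=False).tail(1)["report_id"]
    out = store.subset(survivors)
    removed = len(r) - len(out.reports)
    out = out.with_provenance(dedup={"before": len(r), "after": len(out.reports),
                                     "removed": removed})
    out.log(f"deduplicate: removed {removed} of {len(r)} reports")
    return out


def filter_primary_suspect(store: ReportStore, drug_names: Sequence[str],
                           aliases: Optional[Mapping[str, str]] = None) -> ReportStore:
    """Restrict to reports naming one of ``drug_names`` as primary suspect.

    ``aliases`` maps alternate spellings (brand names) to the canonical
    name; matching is on normalized (lower-case, alphanumeric) strings.
    """
    if not drug_names:
        raise ValueError("drug_names must be non-empty")
    targets = {normalize_drug_name(d) for d in drug_names}
    alias_map = {normalize_drug_name(k): normalize_drug_name(v)
                 for k, v in (aliases or {}).items()}
    drugs = store.drugs
    canon = drugs["drug"].map(normalize_drug_name).map(lambda d: alias_map.get(d, d))
    hit = (drugs["role"] == "PS") & canon.isin(targets)
    keep_ids = drugs.loc[hit, "report_id"].unique()
    if len(keep_ids) == 0:
        warnings.warn("filter_primary_suspect: no reports matched; empty cohort")
    out = store.subset(keep_ids)
    out = out.with_provenance(ps_filter={"drugs": sorted(targets),
                                         "before": store.n_reports,
                                         "after": out.n_reports})
    out.log(f"filter_primary_suspect: kept {out.n_reports} of {store.n_reports} reports")
    return out
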