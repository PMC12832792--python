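"""Reading and writing spontaneous-report tables.

Two external forms are supported:

* the quarterly ASCII dialect used by the FDA adverse-event reporting
  system: one ``$``-delimited file per table (DEMO, DRUG, REAC, THER,
  OUTC, INDI) with a single header line, joined on ``primaryid``;
* a single flat CSV with one row per (report, reaction) pair.

Parsing is deliberately forgiving about values (bad dates or implausible
ages become missing, and are logged) but strict about structure (a missing
mandatory column is a hard error naming the file and column).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .records import AGE_BOUNDS, WEIGHT_BOUNDS, ReportStore, Vocabulary

DELIM = "$"

# multipliers to years, keyed by the age-unit code column
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

WEIGHT_UNIT_TO_KG = {"KG": 1.0, "LBS": 0.45359237, "GMS": 0.001}

REPORTER_CODES = {"MD": "physician", "PH": "pharmacist", "CN": "consumer",
                  "HP": "other_hp", "OT": "other_hp"}

SEX_CODES = {"M": "male", "F": "female"}

KNOWN_OUTCOMES = {"DE", "LT", "HO", "DS", "OT"}

MANDATORY = {
    "demo": ["primaryid", "caseid", "fda_dt", "sex", "age", "age_cod",
             "wt", "wt_cod", "occp_cod", "occr_country", "event_dt"],
    "drug": ["primaryid", "drugname", "role_cod"],
    "reac": ["primaryid", "pt"],
    "ther": ["primaryid", "start_dt"],
    "outc": ["primaryid", "outc_cod"],
    "indi": ["primaryid", "indi_pt"],
}


def normalize_drug_name(name: str) -> str:
    """Lower-case and strip whitespace/punctuation so brand spellings match."""
    if not isinstance(name, str):
        return ""
    return "".join(ch for ch in name.lower() if ch.isalnum())


def _read_table(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=DELIM, dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in MANDATORY[table]:
        if col not in df.columns:
            raise ValueError(f"{path}: mandatory column {col!r} missing from {table.upper()} table")
    return df.replace("", np.nan)


def _parse_dates(raw: pd.Series, log: list, what: str) -> pd.Series:
    """yyyymmdd strings -> Timestamps; anything unparseable becomes NaT."""
    out = pd.to_datetime(raw, format="%Y%m%d", errors="coerce")
    bad = raw.notna() & out.isna()
    if bad.any():
        log.append(f"{what}: {int(bad.sum())} unparseable dates set missing")
    return out


def _parse_age(age: pd.Series, unit: pd.Series, log: list) -> pd.Series:
    mult = unit.str.upper().map(AGE_UNIT_TO_YEARS)
    mult = mult.fillna(1.0)  # missing unit code: assume years
    years = pd.to_numeric(age, errors="coerce") * mult
    out_of_range = years.notna() & ~years.between(*AGE_BOUNDS)
    if out_of_range.any():
        log.append(f"DEMO: {int(out_of_range.sum())} ages outside {AGE_BOUNDS} set missing")
    return years.mask(out_of_range)


def _parse_weight(wt: pd.Series, unit: pd.Series, log: list) -> pd.Series:
    mult = unit.str.upper().map(WEIGHT_UNIT_TO_KG).fillna(1.0)
    kg = pd.to_numeric(wt, errors="coerce") * mult
    out_of_range = kg.notna() & ~kg.between(*WEIGHT_BOUNDS)
    if out_of_range.any():
        log.append(f"DEMO: {int(out_of_range.sum())} weights outside {WEIGHT_BOUNDS} set missing")
    return kg.mask(out_of_range)


def read_faers_tables(paths: Mapping[str, str | Path], vocabulary: Vocabulary) -> ReportStore:
    """Assemble a :class:`ReportStore` from per-table dollar-delimited files.

    Parameters
    ----------
    paths
        Mapping with keys ``demo, drug, reac`` (mandatory) and optionally
        ``ther, outc, indi``.
    vocabulary
        PT/SOC vocabulary attached to the resulting store.

    Reports present in DEMO but without any reaction row are dropped (a
    report must describe at least one adverse event); child rows whose
    ``primaryid`` is unknown are skipped with a warning.
    """
    log: list = []
    for key in ("demo", "drug", "reac"):
        if key not in paths:
            raise ValueError(f"paths must include the {key.upper()} table")

    demo = _read_table(Path(paths["demo"]), "demo")
    drug = _read_table(Path(paths["drug"]), "drug")
    reac = _read_table(Path(paths["reac"]), "reac")
    ther = _read_table(Path(paths["ther"]), "ther") if "ther" in paths else None
    outc = _read_table(Path(paths["outc"]), "outc") if "outc" in paths else None
    indi = _read_table(Path(paths["indi"]), "indi") if "indi" in paths else None

    known = set(demo["primaryid"])

    def _drop_orphans(df: Optional[pd.DataFrame], name: str) -> Optional[pd.DataFrame]:
        if df is None:
            return None
        orphan = ~df["primaryid"].isin(known)
        if orphan.any():
            warnings.warn(f"{name}: {int(orphan.sum())} rows reference unknown primaryid; skipped")
            log.append(f"{name}: {int(orphan.sum())} orphan rows skipped")
        return df[~orphan]

    drug = _drop_orphans(drug, "DRUG")
    reac = _drop_orphans(reac, "REAC")
    ther = _drop_orphans(ther, "THER")
    outc = _drop_orphans(outc, "OUTC")
    indi = _drop_orphans(indi, "INDI")

    # a report with no reactions carries no analysable event
    with_reac = set(reac["primaryid"])
    no_reac = ~demo["primaryid"].isin(with_reac)
    if no_reac.any():
        log.append(f"DEMO: {int(no_reac.sum())} reports without reaction rows dropped")
    demo = demo[~no_reac]

    reports = pd.DataFrame({
        "report_id": demo["primaryid"],
        "case_id": demo["caseid"],
        "receipt_date": _parse_dates(demo["fda_dt"], log, "DEMO.fda_dt"),
        "sex": demo["sex"].str.upper().map(SEX_CODES),
        "age_years": _parse_age(demo["age"], demo["age_cod"], log),
        "weight_kg": _parse_weight(demo["wt"], demo["wt_cod"], log),
        "reporter": demo["occp_cod"].str.upper().map(REPORTER_CODES),
        "country": demo["occr_country"],
        "therapy_start": pd.NaT,
        "event_onset": _parse_dates(demo["event_dt"], log, "DEMO.event_dt"),
    }).reset_index(drop=True)

    if ther is not None and len(ther):
        starts = ther.assign(start=_parse_dates(ther["start_dt"], log, "THER.start_dt"))
        first_start = starts.groupby("primaryid")["start"].min()
        reports["therapy_start"] = reports["report_id"].map(first_start)

    keep = set(reports["report_id"])
    drugs = pd.DataFrame({
        "report_id": drug["primaryid"],
        "drug": drug["drugname"].map(normalize_drug_name),
        "role": drug["role_cod"].str.upper(),
    })
    drugs = drugs[drugs["report_id"].isin(keep)].reset_index(drop=True)

    reactions = pd.DataFrame({"report_id": reac["primaryid"], "pt": reac["pt"]})
    reactions = reactions[reactions["report_id"].isin(keep)].drop_duplicates().reset_index(drop=True)

    if outc is not None and len(outc):
        ocode = outc["outc_cod"].str.upper()
        outcomes = pd.DataFrame({
            "report_id": outc["primaryid"],
            "outcome": ocode.where(ocode.isin(KNOWN_OUTCOMES), "OT"),
        })
        outcomes = outcomes[outcomes["report_id"].isin(keep)].drop_duplicates().reset_index(drop=True)
    else:
        outcomes = pd.DataFrame(columns=["report_id", "outcome"])

    if indi is not None and len(indi):
        indications = pd.DataFrame({"report_id": indi["primaryid"], "pt": indi["indi_pt"]})
        indications = indications[indications["report_id"].isin(keep)].reset_index(drop=True)
    else:
        indications = pd.DataFrame(columns=["report_id", "pt"])

    provenance = {
        "source": {k: str(v) for k, v in paths.items()},
        "rows_read": {"demo": len(demo) + int(no_reac.sum()), "drug": len(drugs),
                      "reac": len(reactions)},
        "n_reports": len(reports),
        "log": log,
    }
    return ReportStore(reports, drugs, reactions, outcomes, indications, vocabulary, provenance)


# ---------------------------------------------------------------------------
# writer (round-trips through read_faers_tables)

def _fmt_date(s: pd.Series) -> pd.Series:
    return s.dt.strftime("%Y%m%d")


def write_faers_dialect(store: ReportStore, out_dir: str | Path) -> dict:
    """Emit DEMO/DRUG/REAC/THER/OUTC/INDI dollar-delimited files.

    Returns the mapping of table name to file path, suitable for feeding
    straight back into :func:`read_faers_tables`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = store.reports
    inv_sex = {v: k for k, v in SEX_CODES.items()}
    inv_rep = {"physician": "MD", "pharmacist": "PH", "consumer": "CN", "other_hp": "OT"}

    demo = pd.DataFrame({
        "primaryid": r["report_id"],
        "caseid": r["case_id"],
        "fda_dt": _fmt_date(r["receipt_date"]),
        "event_dt": _fmt_date(r["event_onset"]),
        "sex": r["sex"].map(inv_sex),
        "age": r["age_years"],
        "age_cod": np.where(r["age_years"].notna(), "YR", ""),
        "wt": r["weight_kg"],
        "wt_cod": np.where(r["weight_kg"].notna(), "KG", ""),
        "occp_cod": r["reporter"].map(inv_rep),
        "occr_country": r["country"],
    })
    ther = pd.DataFrame({
        "primaryid": r["report_id"],
        "dsg_drug_seq": 1,
        "start_dt": _fmt_date(r["therapy_start"]),
    }).dropna(subset=["start_dt"])

    paths = {
        "demo": out / "DEMO.txt", "drug": out / "DRUG.txt", "reac": out / "REAC.txt",
        "ther": out / "THER.txt", "outc": out / "OUTC.txt", "indi": out / "INDI.txt",
    }
    demo.to_csv(paths["demo"], sep=DELIM, index=False)
    store.drugs.rename(columns={"report_id": "primaryid", "drug": "drugname",
                                "role": "role_cod"}).to_csv(paths["drug"], sep=DELIM, index=False)
    store.reactions.rename(columns={"report_id": "primaryid"}).to_csv(paths["reac"], sep=DELIM, index=False)
    ther.to_csv(paths["ther"], sep=DELIM, index=False)
    store.outcomes.rename(columns={"report_id": "primaryid", "outcome": "outc_cod"}).to_csv(
        paths["outc"], sep=DELIM, index=False)
    store.indications.assign(indi_drug_seq=1).rename(
        columns={"report_id": "primaryid", "pt": "indi_pt"})[
        ["primaryid", "indi_drug_seq", "indi_pt"]].to_csv(paths["indi"], sep=DELIM, index=False)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# flat CSV (one row per report-reaction pair)

FLAT_COLUMNS = ["report_id", "case_id", "receipt_date", "pt", "ps_drug", "sex",
                "age_years", "weight_kg", "reporter", "country", "outcomes",
                "indications", "therapy_start", "event_onset"]


def write_flat_csv(store: ReportStore, path: str | Path) -> None:
    outc = store.outcomes.groupby("report_id")["outcome"].apply(lambda s: ";".join(sorted(s)))
    indi = store.indications.groupby("report_id")["pt"].apply(lambda s: ";".join(s))
    flat = store.reactions.merge(store.reports, on="report_id", how="left")
    flat["ps_drug"] = flat["report_id"].map(store.ps_drug())
    flat["outcomes"] = flat["report_id"].map(outc)
    flat["indications"] = flat["report_id"].map(indi)
    flat[FLAT_COLUMNS].to_csv(path, index=False)


def read_flat_csv(path: str | Path, vocabulary: Vocabulary) -> ReportStore:
    flat = pd.read_csv(path, dtype={"report_id": str, "case_id": str},
                       parse_dates=["receipt_date", "therapy_start", "event_onset"])
    missing = [c for c in FLAT_COLUMNS if c not in flat.columns]
    if missing:
        raise ValueError(f"{path}: mandatory columns missing from flat CSV: {missing}")
    per_report = flat.drop_duplicates("report_id")
    reports = per_report[["report_id", "case_id", "receipt_date", "sex", "age_years",
                          "weight_kg", "reporter", "country", "therapy_start",
                          "event_onset"]].reset_index(drop=True)
    drugs = per_report[["report_id", "ps_drug"]].dropna().rename(columns={"ps_drug": "drug"})
    drugs["role"] = "PS"
    reactions = flat[["report_id", "pt"]].drop_duplicates().reset_index(drop=True)

    def _split(series_name):
        rows = []
        for rid, val in zip(per_report["report_id"], per_report[series_name]):
            if isinstance(val, str) and val:
                rows.extend((rid, tok) for tok in val.split(";"))
        return rows

    outcomes = pd.DataFrame(_split("outcomes"), columns=["report_id", "outcome"])
    indications = pd.DataFrame(_split("indications"), columns=["report_id", "pt"])
    prov = {"source": {"flat_csv": str(path)}, "n_reports": len(reports), "log": []}
    return ReportStore(reports, drugs.reset_index(drop=True), reactions, outcomes,
                       indications, vocabulary, prov)
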