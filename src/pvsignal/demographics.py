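"""Descriptive summaries of a report cohort.

Produces the standard baseline-characteristics table: counts and
percentages of all reports by sex, age band, weight band, reporter type,
worst outcome, country and indication, with missingness reported as its
own level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import ReportStore

AGE_BANDS = [(-np.inf, 18, "<18"), (18, 65, "18-64"), (65, 86, "65-85"), (86, np.inf, ">85")]
WEIGHT_BANDS = [(-np.inf, 50, "<50"), (50, 100.000001, "50-100"), (100.000001, np.inf, ">100")]

#: precedence for collapsing multi-outcome reports to a single worst outcome
OUTCOME_PRECEDENCE = ["DE", "LT", "DS", "HO", "OT"]
OUTCOME_LABELS = {"DE": "death", "LT": "life_threatening", "DS": "disability",
                  "HO": "hospitalization", "OT": "others"}


def percent(count: int, total: int) -> float:
    """Share of all reports, in percent, rounded to two decimals."""
    return round(100.0 * count / total, 2)


def _band(values: pd.Series, bands) -> pd.Series:
    out = pd.Series("missing", index=values.index, dtype=object)
    for lo, hi, label in bands:
        out[values.notna() & (values >= lo) & (values < hi)] = label
    return out


def worst_outcome(store: ReportStore) -> pd.Series:
    """One outcome label per report: the most severe listed code, or
    ``others`` when no severe code (or no outcome row) is present."""
    rank = {code: i for i, code in enumerate(OUTCOME_PRECEDENCE)}
    oc = store.outcomes.copy()
    if len(oc):
        oc["rank"] = oc["outcome"].map(rank)
        best = oc.sort_values("rank").groupby("report_id")["outcome"].first()
    else:
        best = pd.Series(dtype=object)
    labels = store.reports["report_id"].map(best).map(OUTCOME_LABELS).fillna("others")
    labels.index = store.reports["report_id"]
    return labels


def summarize_demographics(store: ReportStore, top_countries: int = 5,
                           top_indications: int = 3) -> pd.DataFrame:
    """Baseline table with columns (category, level, count, percent).

    Percentages are relative to all reports in the store; within each
    exhaustive single-valued category (sex, age, weight, outcome) they sum
    to 100 up to rounding.
    """
    total = store.n_reports
    rows: list = []
    if total == 0:
        return pd.DataFrame(columns=["category", "level", "count", "percent"])

    def _add(category: str, counts: pd.Series, order=None) -> None:
        if order is None:
            order = list(counts.index)
        for level in order:
            c = int(counts.get(level, 0))
            rows.append((category, level, c, percent(c, total)))

    rows.append(("all", "all_reports", total, percent(total, total)))

    sex = store.reports["sex"].fillna("missing")
    _add("sex", sex.value_counts(), ["female", "male", "missing"])

    age = _band(store.reports["age_years"], AGE_BANDS)
    _add("age_years", age.value_counts(), [b[2] for b in AGE_BANDS] + ["missing"])

    weight = _band(store.reports["weight_kg"], WEIGHT_BANDS)
    _add("weight_kg", weight.value_counts(), [b[2] for b in WEIGHT_BANDS] + ["missing"])

    reporter = store.reports["reporter"].fillna("missing")
    _add("reporter", reporter.value_counts(),
         ["physician", "consumer", "pharmacist", "other_hp", "missing"])

    _add("outcome", worst_outcome(store).value_counts(),
         [OUTCOME_LABELS[c] for c in OUTCOME_PRECEDENCE])

    country = store.reports["country"].fillna("missing")
    _add("country", country.value_counts().head(top_countries))

    if len(store.indications):
        indi = store.indications.drop_duplicates().groupby("pt")["report_id"].nunique()
        _add("indication", indi.sort_values(ascending=False).head(top_indications))

    return pd.DataFrame(rows, columns=["category", "level", "count", "percent"])
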