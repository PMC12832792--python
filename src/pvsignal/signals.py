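"""Four-algorithm signal screening with positivity flags.

For every event reported with the target drug, the screen computes the
reporting odds ratio, the proportional reporting ratio with chi-square,
the BCPNN information component, and the empirical-Bayes geometric mean,
then applies the conventional positivity criteria:

=========  ===============================================
ROR        a >= 3 and lower 95% CI bound > 1
PRR        PRR >= 2 and chi2 >= 4 and a >= 3
BCPNN      IC025 > 0
MGPS       EBGM05 > 2
=========  ===============================================

``positive_any`` (the inclusive screen: flagged by at least one
algorithm) and ``positive_all`` (flagged by all four) are both reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import mgps
from .contingency import all_pair_counts, pair_counts
from .records import ReportStore
from .stats import bcpnn_ic, prr_vec, ror_vec

#: age strata used in subgroup screening: [0,18), [18,65), [65,inf)
AGE_BIN_EDGES = (18.0, 65.0)


@dataclass(frozen=True)
class Thresholds:
    """Positivity criteria for the four algorithms; all configurable."""

    ror_min_a: int = 3
    ror_ci_lo: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_min_a: int = 3
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass(frozen=True)
class SignalResult:
    """All four statistics plus flags for one (drug, event) pair."""

    drug: str
    event: str
    level: str
    a: int
    ror: float
    ror_ci95: Tuple[float, float]
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: Dict[str, bool] = field(default_factory=dict)
    positive_any: bool = False
    positive_all: bool = False


SIGNAL_COLUMNS = ["drug", "event", "level", "a", "b", "c", "d", "expected",
                  "ror", "ror_lo", "ror_hi", "ror_corrected", "prr", "chi2",
                  "ic", "ic025", "ebgm", "ebgm05",
                  "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps",
                  "positive_any", "positive_all"]


def evaluate_signals(store: ReportStore, drug: str, level: str = "PT",
                     thresholds: Optional[Thresholds] = None,
                     prior: Optional[mgps.MgpsPrior] = None,
                     min_count: int = 1) -> pd.DataFrame:
    """Screen every event of the store against the target drug.

    Returns one row per event with count >= ``min_count`` under the drug,
    columns :data:`SIGNAL_COLUMNS`, sorted by ``a`` descending.  When no
    fitted MGPS ``prior`` is passed, one is fitted on the store's full
    (primary-suspect drug, event) universe at the same level.
    """
    th = thresholds or Thresholds()
    counts = pair_counts(store, drug, level)
    counts = counts[counts["a"] >= min_count]
    a = counts["a"].to_numpy(float)
    b = counts["b"].to_numpy(float)
    c = counts["c"].to_numpy(float)
    d = counts["d"].to_numpy(float)
    n = a + b + c + d
    expected = (a + b) * (a + c) / n

    ror_est, ror_lo, ror_hi, corrected = ror_vec(a, b, c, d)
    prr_est, chi2 = prr_vec(a, b, c, d)
    ic, ic025 = bcpnn_ic(a, expected)

    if prior is None:
        universe = all_pair_counts(store, level)
        prior = mgps.fit_prior(universe["a"], universe["E"])
    ebgm_est = mgps.ebgm(a, expected, prior)
    eb05 = np.atleast_1d(mgps.ebgm05(a, expected, prior))

    flag_ror = (a >= th.ror_min_a) & (ror_lo > th.ror_ci_lo)
    flag_prr = (prr_est >= th.prr_min) & (chi2 >= th.chi2_min) & (a >= th.prr_min_a)
    flag_bcpnn = ic025 > th.ic025_min
    flag_mgps = eb05 > th.ebgm05_min
    any_ = flag_ror | flag_prr | flag_bcpnn | flag_mgps
    all_ = flag_ror & flag_prr & flag_bcpnn & flag_mgps

    out = pd.DataFrame({
        "drug": drug, "event": counts.index, "level": level,
        "a": a.astype(int), "b": b.astype(int), "c": c.astype(int), "d": d.astype(int),
        "expected": expected,
        "ror": ror_est, "ror_lo": ror_lo, "ror_hi": ror_hi, "ror_corrected": corrected,
        "prr": prr_est, "chi2": chi2, "ic": ic, "ic025": ic025,
        "ebgm": ebgm_est, "ebgm05": eb05,
        "flag_ror": flag_ror, "flag_prr": flag_prr,
        "flag_bcpnn": flag_bcpnn, "flag_mgps": flag_mgps,
        "positive_any": any_, "positive_all": all_,
    })
    return out.sort_values(["a", "event"], ascending=[False, True]).reset_index(drop=True)


def signal_results(frame: pd.DataFrame) -> List[SignalResult]:
    """Dataclass view of an :func:`evaluate_signals` frame."""
    out = []
    for r in frame.itertuples(index=False):
        flags = {"ror": bool(r.flag_ror), "prr": bool(r.flag_prr),
                 "bcpnn": bool(r.flag_bcpnn), "mgps": bool(r.flag_mgps)}
        out.append(SignalResult(r.drug, r.event, r.level, int(r.a), float(r.ror),
                                (float(r.ror_lo), float(r.ror_hi)), float(r.prr),
                                float(r.chi2), float(r.ic), float(r.ic025),
                                float(r.ebgm), float(r.ebgm05), flags,
                                bool(r.positive_any), bool(r.positive_all)))
    return out


def forest_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (event, ror, lo, hi, n) table for forest plots."""
    return frame.rename(columns={"ror_lo": "lo", "ror_hi": "hi", "a": "n"})[
        ["event", "ror", "lo", "hi", "n"]]


# ---------------------------------------------------------------------------
# subgroup screening


@dataclass
class SubgroupScreen:
    """Per-stratum screens plus the shared/exclusive partition of positives."""

    per_stratum: Dict[str, pd.DataFrame]
    shared: List[str]
    exclusive: Dict[str, List[str]]  # per stratum, ranked by report count


def _strata(store: ReportStore, stratifier: str) -> Dict[str, pd.Series]:
    r = store.reports
    if stratifier == "sex":
        return {s: r.loc[r["sex"] == s, "report_id"] for s in ("male", "female")}
    if stratifier == "age_bins":
        lo, hi = AGE_BIN_EDGES
        age = r["age_years"]
        return {
            "<18": r.loc[age.notna() & (age < lo), "report_id"],
            "18-65": r.loc[age.notna() & (age >= lo) & (age < hi), "report_id"],
            ">=65": r.loc[age.notna() & (age >= hi), "report_id"],
        }
    raise ValueError(f"unknown stratifier {stratifier!r}")


def subgroup_screen(store: ReportStore, stratifier: str, drug: str,
                    thresholds: Optional[Thresholds] = None, level: str = "PT",
                    criterion: str = "positive_any", min_count: int = 1) -> SubgroupScreen:
    """Re-run the screen inside each stratum of ``sex`` or ``age_bins``.

    Contingency tables are rebuilt within the stratum, so the comparator
    background is the same stratum; reports missing the stratifier are
    excluded.  ``criterion`` names the flag column defining a positive
    (e.g. ``flag_ror`` for a ROR-only screen, ``positive_all`` for the
    strict four-algorithm rule).
    """
    screens: Dict[str, pd.DataFrame] = {}
    positives: Dict[str, pd.DataFrame] = {}
    for name, ids in _strata(store, stratifier).items():
        sub = store.subset(ids)
        drug_reports = sub.drugs[(sub.drugs["role"] == "PS") & (sub.drugs["drug"] == drug)]
        if len(drug_reports) == 0:
            warnings.warn(f"stratum {name!r} has no target-drug reports; empty screen")
            screens[name] = pd.DataFrame(columns=SIGNAL_COLUMNS)
            positives[name] = screens[name]
            continue
        frame = evaluate_signals(sub, drug, level, thresholds, min_count=min_count)
        screens[name] = frame
        positives[name] = frame[frame[criterion]]

    pos_sets = {k: set(v["event"]) for k, v in positives.items()}
    shared = set.intersection(*pos_sets.values()) if pos_sets else set()
    exclusive = {}
    for name, events in pos_sets.items():
        others = set.union(*(s for k, s in pos_sets.items() if k != name), set())
        excl = events - others
        ranked = positives[name][positives[name]["event"].isin(excl)]
        exclusive[name] = list(ranked.sort_values("a", ascending=False)["event"])
    return SubgroupScreen(screens, sorted(shared), exclusive)
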