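"""Semi-quantitative clinical prioritization of positive signals.

Each signal is scored 0/1/2 on four dimensions — reporting rate, signal
stability across three designated disproportionality algorithms, reported
case fatality rate, and membership of the designated/important medical
event (DME/IME) lists — and the total (0-8) is banded into low (0-2),
moderate (3-5) or high (6-8) clinical priority.

Boundary conventions (pinned by tests): a reporting rate of exactly 10%
scores 1 (the 2-point band is strictly above 10%); fatality rates of
exactly 25% or 50% score 1 (the middle band is read inclusive on both
ends).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from .records import ReportStore, Vocabulary

#: algorithms counted for the stability dimension (three designated;
#: the screen's remaining algorithm is treated as the headline filter)
DEFAULT_STABILITY_ALGORITHMS = ("prr", "bcpnn", "mgps")

PRIORITY_BANDS = {"low": (0, 2), "moderate": (3, 5), "high": (6, 8)}


@dataclass(frozen=True)
class PriorityScore:
    event: str
    reporting_rate: float
    rate_score: int
    stability_count: int
    stability_score: int
    fatality_rate: float
    fatality_score: int
    dme_ime_score: int
    total: int
    priority_class: str


def score_reporting_rate(event_cases: int, drug_total_reports: int) -> Tuple[float, int]:
    """2 points above 10%, 1 point in (1%, 10%], 0 at or below 1%."""
    if drug_total_reports <= 0:
        raise ValueError("drug_total_reports must be positive")
    if event_cases > drug_total_reports:
        raise ValueError("event_cases cannot exceed drug_total_reports")
    rate = event_cases / drug_total_reports
    score = 2 if rate > 0.10 else (1 if rate > 0.01 else 0)
    return rate, score


def score_stability(flags: Dict[str, bool],
                    algorithms: Sequence[str] = DEFAULT_STABILITY_ALGORITHMS) -> Tuple[int, int]:
    """Count of positives among the three designated algorithms: 3 of 3
    scores 2, 2 of 3 scores 1, otherwise 0."""
    if len(algorithms) != 3:
        raise ValueError("exactly 3 algorithms must be designated for stability scoring")
    count = sum(bool(flags[alg]) for alg in algorithms)
    score = 2 if count == 3 else (1 if count == 2 else 0)
    return count, score


def score_fatality(death_outcome_reports: int, event_reports: int) -> Tuple[float, int]:
    """2 points above 50%, 1 point in [25%, 50%], 0 below 25%."""
    if event_reports <= 0:
        raise ValueError("event_reports must be positive")
    rate = death_outcome_reports / event_reports
    score = 2 if rate > 0.5 else (1 if rate >= 0.25 else 0)
    return rate, score


def score_dme_ime(event: str, vocab: Vocabulary) -> int:
    """2 for a designated medical event, 1 for an important medical event,
    0 otherwise (DME takes precedence when listed in both)."""
    if event in vocab.dme_terms:
        return 2
    if event in vocab.ime_terms:
        return 1
    return 0


def classify_priority(total: int) -> str:
    if not 0 <= total <= 8:
        raise ValueError(f"total score {total} outside 0-8")
    for label, (lo, hi) in PRIORITY_BANDS.items():
        if lo <= total <= hi:
            return label
    raise AssertionError("unreachable")


def score_signal(event: str, event_cases: int, drug_total_reports: int,
                 flags: Dict[str, bool], death_outcome_reports: int,
                 vocab: Vocabulary,
                 algorithms: Sequence[str] = DEFAULT_STABILITY_ALGORITHMS) -> PriorityScore:
    rate, rate_sc = score_reporting_rate(event_cases, drug_total_reports)
    count, stab_sc = score_stability(flags, algorithms)
    frate, fat_sc = score_fatality(death_outcome_reports, max(event_cases, 1))
    dme_sc = score_dme_ime(event, vocab)
    total = rate_sc + stab_sc + fat_sc + dme_sc
    return PriorityScore(event, rate, rate_sc, count, stab_sc, frate, fat_sc,
                         dme_sc, total, classify_priority(total))


def death_counts(store: ReportStore, level: str = "PT") -> pd.Series:
    """Per event: number of its reports listing death (DE) as an outcome."""
    death_ids = set(store.outcomes.loc[store.outcomes["outcome"] == "DE", "report_id"])
    reac = store.reactions
    if level == "SOC":
        reac = reac.assign(pt=reac["pt"].map(store.vocabulary.soc_of)).drop_duplicates()
    dead = reac[reac["report_id"].isin(death_ids)]
    return dead.groupby("pt")["report_id"].nunique()


def prioritize_signals(signal_frame: pd.DataFrame, store: ReportStore,
                       criterion: str = "positive_all",
                       algorithms: Sequence[str] = DEFAULT_STABILITY_ALGORITHMS,
                       vocab: Optional[Vocabulary] = None) -> pd.DataFrame:
    """Score every signal meeting ``criterion``; returns the priority table
    sorted by total score descending.

    ``signal_frame`` is the output of
    :func:`pvsignal.signals.evaluate_signals` on ``store``.  The
    reporting-rate denominator is the number of reports naming the target
    drug as primary suspect; the fatality numerator counts that cohort's
    reports listing the event together with a death outcome.
    """
    vocab = vocab or store.vocabulary
    level = signal_frame["level"].iloc[0] if len(signal_frame) else "PT"
    drug = signal_frame["drug"].iloc[0] if len(signal_frame) else ""
    ps = store.drugs[(store.drugs["role"] == "PS") & (store.drugs["drug"] == drug)]
    drug_total = ps["report_id"].nunique()
    deaths = death_counts(store.subset(ps["report_id"].unique()), level)

    rows = []
    for r in signal_frame[signal_frame[criterion]].itertuples(index=False):
        flags = {"ror": bool(r.flag_ror), "prr": bool(r.flag_prr),
                 "bcpnn": bool(r.flag_bcpnn), "mgps": bool(r.flag_mgps)}
        sc = score_signal(r.event, int(r.a), drug_total, flags,
                          int(deaths.get(r.event, 0)), vocab, algorithms)
        rows.append(sc)
    frame = pd.DataFrame([vars(s) for s in rows])
    if len(frame):
        frame = frame.sort_values(["total", "reporting_rate"],
                                  ascending=False).reset_index(drop=True)
    return frame
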