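"""Time-to-onset (TTO) analysis.

TTO is the interval in whole days between therapy start and event onset.
Reports missing either date, with onset before start, or with implausibly
long intervals are excluded (and logged by reason); a same-day onset is
coded as 1 day, so the minimum observable TTO is 1.

The temporal pattern is characterized by a two-parameter Weibull fit:
shape beta < 1 indicates an early-failure hazard (events concentrate soon
after treatment start), beta = 1 a memoryless (random) profile, beta > 1 a
wear-out profile increasing with time.  The label is assigned from the
95% CI of beta: "early" when its upper bound is below 1, "wear_out" when
its lower bound exceeds 1, otherwise "random".

Because a spontaneous report exists only once its event has occurred,
there is no censoring; Kaplan-Meier curves are purely descriptive and the
log-rank test compares observed event-time distributions between strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize

from .records import ReportStore

MAX_PLAUSIBLE_DAYS = 3650

TTO_BINS = [(1, 30), (31, 60), (61, 90), (91, 180), (181, 360), (361, None)]


@dataclass
class WeibullFit:
    shape_beta: float
    scale_alpha: float
    ci95_beta: Tuple[float, float]
    ci95_alpha: Tuple[float, float]
    failure_type: str  # early | random | wear_out
    n: int
    median: float
    iqr: Tuple[float, float]
    loglik: float


# ---------------------------------------------------------------------------
# extraction


def extract_tto(store: ReportStore, drug: Optional[str] = None,
                same_day_as_one: bool = True,
                max_days: int = MAX_PLAUSIBLE_DAYS) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """TTO records plus an exclusion log keyed by reason.

    Returns ``(frame, exclusions)`` where ``frame`` has one row per usable
    report with columns ``report_id, tto_days, sex, age_years`` and
    ``exclusions`` counts reports dropped for ``missing_dates``,
    ``onset_before_start``, ``implausible`` and (when ``same_day_as_one``
    is off) ``same_day``.
    """
    r = store.reports
    if drug is not None:
        ps = store.drugs[(store.drugs["role"] == "PS") & (store.drugs["drug"] == drug)]
        r = r[r["report_id"].isin(set(ps["report_id"]))]
    delta = (r["event_onset"] - r["therapy_start"]).dt.days

    missing = delta.isna()
    negative = delta < 0
    same_day = delta == 0
    tto = delta.where(~same_day, 1.0) if same_day_as_one else delta
    implausible = tto > max_days

    keep = ~(missing | negative | implausible)
    if not same_day_as_one:
        keep &= ~same_day
    exclusions = {
        "missing_dates": int(missing.sum()),
        "onset_before_start": int(negative.sum()),
        "implausible": int((implausible & ~missing).sum()),
    }
    if not same_day_as_one:
        exclusions["same_day"] = int(same_day.sum())
    frame = pd.DataFrame({
        "report_id": r.loc[keep, "report_id"].values,
        "tto_days": tto[keep].astype(int).values,
        "sex": r.loc[keep, "sex"].values,
        "age_years": r.loc[keep, "age_years"].values,
    })
    return frame.reset_index(drop=True), exclusions


def summarize_tto(tto_days: Sequence[float]) -> Dict[str, float]:
    """Median and linear-interpolation quartiles, plus min/max and n."""
    t = np.asarray(tto_days, dtype=float)
    if t.size == 0:
        raise ValueError("no TTO records to summarize")
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return {"n": int(t.size), "min": float(t.min()), "max": float(t.max()),
            "median": float(med), "q1": float(q1), "q3": float(q3)}


# ---------------------------------------------------------------------------
# Weibull maximum likelihood


def _shape_equation(beta: float, t: np.ndarray, log_t: np.ndarray) -> float:
    tb = t**beta
    return float((tb * log_t).sum() / tb.sum() - 1.0 / beta - log_t.mean())


def weibull_mle(tto_days: Sequence[float]) -> WeibullFit:
    """Two-parameter Weibull fit by profile maximum likelihood.

    The shape is the root of the standard profile score equation (solved
    by bracketed 1-D root-finding; the equation is monotone in beta), the
    scale follows in closed form, and 95% CIs come from the observed
    information of the (log alpha, log beta) parametrization.
    """
    t = np.asarray(tto_days, dtype=float)
    if t.size < 10:
        raise ValueError("Weibull fit requires at least 10 observations")
    if np.any(t <= 0):
        raise ValueError("all TTO values must be positive")
    if np.all(t == t[0]):
        raise ValueError("degenerate sample: all TTO values identical")
    log_t = np.log(t)

    lo, hi = 1e-3, 1.0
    while _shape_equation(hi, t, log_t) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("Weibull shape root bracket expansion failed")
    beta = optimize.brentq(_shape_equation, lo, hi, args=(t, log_t), xtol=1e-12)
    alpha = (np.mean(t**beta)) ** (1.0 / beta)

    n = t.size
    loglik = float(n * (np.log(beta) - beta * np.log(alpha))
                   + (beta - 1) * log_t.sum() - np.sum((t / alpha) ** beta))

    # observed information in (log alpha, log beta) by central differences
    def _nll(theta):
        la, lb = theta
        al, be = np.exp(la), np.exp(lb)
        return -(n * (np.log(be) - be * np.log(al)) + (be - 1) * log_t.sum()
                 - np.sum((t / al) ** be))

    theta = np.array([np.log(alpha), np.log(beta)])
    h = 1e-5
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            H[i, j] = (_nll(theta + ei + ej) - _nll(theta + ei - ej)
                       - _nll(theta - ei + ej) + _nll(theta - ei - ej)) / (4 * h * h)
    cov = np.linalg.inv(H)
    se_la, se_lb = np.sqrt(np.diag(cov))
    z = 1.959963984540054
    ci_alpha = (float(np.exp(theta[0] - z * se_la)), float(np.exp(theta[0] + z * se_la)))
    ci_beta = (float(np.exp(theta[1] - z * se_lb)), float(np.exp(theta[1] + z * se_lb)))

    if ci_beta[1] < 1.0:
        ftype = "early"
    elif ci_beta[0] > 1.0:
        ftype = "wear_out"
    else:
        ftype = "random"

    s = summarize_tto(t)
    return WeibullFit(float(beta), float(alpha), ci_beta, ci_alpha, ftype,
                      n, s["median"], (s["q1"], s["q3"]), loglik)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMCurve:
    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def km_curve(tto_days: Sequence[float], label: str = "all") -> KMCurve:
    """Product-limit curve; with no censoring this equals 1 - ECDF."""
    t = np.asarray(tto_days, dtype=float)
    if t.size == 0:
        raise ValueError("empty group for Kaplan-Meier curve")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=np.ones_like(t), label=label)
    times = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_[label].to_numpy(float)
    # at-risk counts at each tabulated time
    at_risk = np.array([(t >= u).sum() for u in times])
    return KMCurve(label, times, surv, at_risk)


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p_value: float


def logrank_test(groups: Dict[str, Sequence[float]]) -> LogRankResult:
    """k-sample log-rank test; ties handled via the hypergeometric
    variance at shared event times (all observations are events)."""
    labels, durations = [], []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        labels.extend([name] * v.size)
        durations.extend(v.tolist())
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(np.asarray(durations), np.asarray(labels),
                                    np.ones(len(durations)))
    return LogRankResult(float(res.test_statistic), len(groups) - 1, float(res.p_value))


def tto_histogram(tto_days: Sequence[float], bins=None) -> pd.DataFrame:
    """Counts and proportions in the standard onset windows.

    Bins are inclusive on both ends (a TTO of exactly 30 falls in 1-30);
    the last bin is open-ended.
    """
    t = np.asarray(tto_days, dtype=float)
    if t.size == 0:
        raise ValueError("no TTO records to bin")
    bins = bins or TTO_BINS
    rows = []
    for lo, hi in bins:
        if hi is None:
            count = int((t >= lo).sum())
            label = f">{lo - 1}"
        else:
            count = int(((t >= lo) & (t <= hi)).sum())
            label = f"{lo}-{hi}"
        rows.append((label, count, count / t.size))
    return pd.DataFrame(rows, columns=["bin", "count", "proportion"])


def stratified_weibull(tto_frame: pd.DataFrame) -> pd.DataFrame:
    """Weibull fits and quartile summaries for all reports and the sex and
    age strata, one row per stratum (mirrors the usual published layout)."""
    strata = {"all": tto_frame}
    for s in ("male", "female"):
        strata[f"sex:{s}"] = tto_frame[tto_frame["sex"] == s]
    age = tto_frame["age_years"]
    strata["age:<18"] = tto_frame[age.notna() & (age < 18)]
    strata["age:18-65"] = tto_frame[age.notna() & (age >= 18) & (age < 65)]
    strata["age:>=65"] = tto_frame[age.notna() & (age >= 65)]
    rows = []
    for name, sub in strata.items():
        if len(sub) < 10:
            continue
        fit = weibull_mle(sub["tto_days"])
        rows.append({
            "stratum": name, "n": fit.n, "median": fit.median,
            "q1": fit.iqr[0], "q3": fit.iqr[1],
            "scale_alpha": fit.scale_alpha, "scale_lo": fit.ci95_alpha[0],
            "scale_hi": fit.ci95_alpha[1],
            "shape_beta": fit.shape_beta, "shape_lo": fit.ci95_beta[0],
            "shape_hi": fit.ci95_beta[1], "failure_type": fit.failure_type,
        })
    return pd.DataFrame(rows)
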