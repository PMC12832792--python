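"""Multivariable logistic regression by iteratively reweighted least
squares (IRLS), with Wald and profile-likelihood confidence intervals.

Used to estimate demographic reporting odds ratios for a designated set
of target events: the response marks reports listing any target term, and
the design holds dummy-coded age band, weight band and sex against stated
reference levels.  Rows with any missing covariate are dropped (and
counted); no imputation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .records import ReportStore

Z95 = 1.959963984540054

#: default bands (years, kg); the first band of each is the reference level
DEFAULT_AGE_BINS = ((0, 18, "<18"), (18, 65, "18-65"), (65, np.inf, ">=65"))
DEFAULT_WEIGHT_BINS = ((0, 80, "<80"), (80, 100, "80-100"), (100, np.inf, ">100"))


@dataclass
class LogisticFit:
    terms: list  # column names, intercept first
    estimates: np.ndarray
    std_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    or_point: np.ndarray
    or_ci95: np.ndarray  # shape (k, 2)
    converged: bool
    separation: bool
    n_used: int
    n_dropped_missing: int
    deviance: float
    cov: np.ndarray


def _assign_band(values: pd.Series, bins) -> pd.Series:
    out = pd.Series(np.nan, index=values.index, dtype=object)
    for lo, hi, label in bins:
        out[values.notna() & (values >= lo) & (values < hi)] = label
    return out


def build_design(store: ReportStore, target_pts: Sequence[str],
                 age_bins=DEFAULT_AGE_BINS,
                 weight_bins=DEFAULT_WEIGHT_BINS) -> Tuple[pd.DataFrame, pd.Series, int]:
    """Design matrix and response for the target-event risk model.

    Response is 1 when the report lists any of ``target_pts``.  Age and
    weight are dummy-coded against the first band; sex against female.
    Returns ``(X, y, n_dropped)`` with an intercept column first.
    """
    r = store.reports
    targets = set(target_pts)
    hits = store.reactions[store.reactions["pt"].isin(targets)]
    y_all = r["report_id"].isin(set(hits["report_id"])).astype(int)

    age_band = _assign_band(r["age_years"], age_bins)
    weight_band = _assign_band(r["weight_kg"], weight_bins)
    sex = r["sex"]

    complete = age_band.notna() & weight_band.notna() & sex.notna()
    n_dropped = int((~complete).sum())
    sub = pd.DataFrame({
        "age_band": age_band[complete],
        "weight_band": weight_band[complete],
        "male": (sex[complete] == "male").astype(float),
    })
    X = pd.DataFrame({"(Intercept)": 1.0}, index=sub.index)
    for _, _, label in age_bins[1:]:
        X[f"age[{label}]"] = (sub["age_band"] == label).astype(float)
    for _, _, label in weight_bins[1:]:
        X[f"weight[{label}]"] = (sub["weight_band"] == label).astype(float)
    X["male"] = sub["male"]
    y = y_all[complete]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("response has zero cases or zero controls after dropping missing rows")
    return X, y, n_dropped


def fit_logistic_irls(X, y, tol: float = 1e-10, max_iter: int = 100,
                      n_dropped_missing: int = 0) -> LogisticFit:
    """Newton/IRLS fit of a binomial GLM with logit link.

    Iterates to gradient sup-norm below ``tol``; standard errors come
    from the inverse observed information at the optimum.  Diverging
    coefficients (|beta| > 30, complete separation) stop the fit with the
    ``separation`` flag set.
    """
    X = pd.DataFrame(X)
    terms = list(X.columns)
    Xm = X.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    n, k = Xm.shape
    if np.linalg.matrix_rank(Xm) < k:
        raise ValueError("design matrix is rank deficient; drop empty levels")

    beta = np.zeros(k)
    converged = False
    separation = False
    for _ in range(max_iter):
        eta = Xm @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xm.T @ (yv - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        info = (Xm * w[:, None]).T @ Xm
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            separation = True
            break

    # a fitted probability pinned at 0/1 for a whole covariate cell shows
    # up as a huge coefficient: quasi-separation, flag it
    if np.max(np.abs(beta)) > 15:
        separation = True

    eta = Xm @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (Xm * w[:, None]).T @ Xm
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * sstats.norm.sf(np.abs(z))
    with np.errstate(divide="ignore"):
        dev = -2.0 * float(np.sum(yv * np.log(np.clip(mu, 1e-300, 1))
                                  + (1 - yv) * np.log(np.clip(1 - mu, 1e-300, 1))))
    with np.errstate(over="ignore"):
        or_point = np.exp(beta)
        or_ci = np.column_stack([np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)])
    return LogisticFit(terms, beta, se, z, p, or_point, or_ci,
                       converged and not separation, separation, n, n_dropped_missing,
                       dev, cov)


def _deviance_at(Xm: np.ndarray, yv: np.ndarray, beta: np.ndarray) -> float:
    mu = 1.0 / (1.0 + np.exp(-(Xm @ beta)))
    mu = np.clip(mu, 1e-300, 1 - 1e-16)
    return -2.0 * float(np.sum(yv * np.log(mu) + (1 - yv) * np.log(1 - mu)))


def profile_ci(X, y, fit: LogisticFit, term: str, level: float = 0.95) -> Tuple[float, float]:
    """Profile-likelihood CI for one coefficient.

    Finds, on each side of the MLE, the coefficient value at which the
    profile deviance (all other coefficients re-optimized) rises by the
    chi-square(1) critical value.
    """
    from scipy import optimize

    Xm = pd.DataFrame(X).to_numpy(float)
    yv = np.asarray(y, dtype=float)
    j = fit.terms.index(term)
    crit = sstats.chi2.ppf(level, 1)
    d0 = fit.deviance
    free = [i for i in range(Xm.shape[1]) if i != j]

    def profile_dev(bj: float) -> float:
        def nll(bfree):
            beta = np.empty(Xm.shape[1])
            beta[j] = bj
            beta[free] = bfree
            return _deviance_at(Xm, yv, beta) / 2.0
        res = optimize.minimize(nll, fit.estimates[free], method="BFGS",
                                options={"gtol": 1e-8})
        return 2.0 * res.fun

    def root(bj):
        return profile_dev(bj) - d0 - crit

    se = fit.std_errors[j]
    bhat = fit.estimates[j]
    lo_br = bhat - 5 * se
    while root(lo_br) < 0:
        lo_br -= 2 * se
    hi_br = bhat + 5 * se
    while root(hi_br) < 0:
        hi_br += 2 * se
    lo = optimize.brentq(root, lo_br, bhat, xtol=1e-6)
    hi = optimize.brentq(root, bhat, hi_br, xtol=1e-6)
    return float(lo), float(hi)


def or_table(fit: LogisticFit, ci: Optional[Dict[str, Tuple[float, float]]] = None) -> pd.DataFrame:
    """Publication-shaped table: one row per non-intercept term with
    estimate, SE, z, OR (95% CI) and p-value; the intercept row keeps its
    estimate but no OR.  ``ci`` optionally overrides the Wald intervals
    (e.g. with profile-likelihood bounds) per term."""
    if not fit.converged:
        raise ValueError("refusing to tabulate a non-converged fit")
    rows = []
    for i, term in enumerate(fit.terms):
        lo, hi = fit.or_ci95[i]
        if ci and term in ci:
            lo, hi = np.exp(ci[term][0]), np.exp(ci[term][1])
        is_int = term == "(Intercept)"
        rows.append({
            "term": term,
            "estimate": round(float(fit.estimates[i]), 2),
            "std_error": round(float(fit.std_errors[i]), 2),
            "z_value": round(float(fit.z_values[i]), 2),
            "or": None if is_int else round(float(fit.or_point[i]), 2),
            "or_lo": None if is_int else round(float(lo), 2),
            "or_hi": None if is_int else round(float(hi), 2),
            "p_value": None if is_int else float(fit.p_values[i]),
        })
    return pd.DataFrame(rows)
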