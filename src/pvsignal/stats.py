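"""Frequentist and closed-form Bayesian disproportionality statistics.

Implements, for a 2x2 table (a, b, c, d):

* reporting odds ratio ROR = ad/bc with a 95% Wald interval on the log
  scale, applying the Haldane-Anscombe 0.5 continuity correction to all
  cells when any cell is zero;
* proportional reporting ratio PRR = [a/(a+b)] / [c/(c+d)] paired with the
  Yates-corrected Pearson chi-square statistic;
* the information component IC = log2[(a+0.5)/(E+0.5)] of the Bayesian
  confidence propagation neural network, with the closed-form lower bound
  of its 95% credible interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .contingency import ContingencyTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class RorResult:
    estimate: float
    ci95: Tuple[float, float]
    corrected: bool  # True when the 0.5 continuity correction was applied


def ror(table: ContingencyTable) -> RorResult:
    """Reporting odds ratio with 95% Wald CI.

    Any zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell), flagged in the result.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(est) - Z95 * se), np.exp(np.log(est) + Z95 * se)
    return RorResult(est, (float(lo), float(hi)), corrected)


def prr(table: ContingencyTable, yates: bool = True) -> Tuple[float, float]:
    """Proportional reporting ratio and its (Yates-corrected) chi-square.

    Returns ``(prr, chi2)``.  When the comparator rate c/(c+d) is zero the
    ratio is undefined and returned as ``nan``; a = 0 gives PRR 0.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    if a + b == 0 or c + d == 0:
        return float("nan"), float("nan")
    drug_rate = a / (a + b)
    other_rate = c / (c + d)
    est = drug_rate / other_rate if other_rate > 0 else float("nan")
    num = abs(a * d - b * c) - (n / 2 if yates else 0.0)
    num = max(num, 0.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * num**2 / denom if denom > 0 else float("nan")
    return float(est), float(chi2)


def bcpnn_ic(a: float | np.ndarray, expected: float | np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Information component and lower 95% credible bound, closed form.

    ``ic = log2[(a+0.5)/(E+0.5)]``; the lower bound subtracts the standard
    two-term expansion of the Gamma-posterior credible interval,
    ``3.3 (a+0.5)^{-1/2} + 2.4 (a+0.5)^{-3/2}``.
    """
    a = np.asarray(a, dtype=float)
    expected = np.asarray(expected, dtype=float)
    ic = np.log2((a + 0.5) / (expected + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.4 * (a + 0.5) ** -1.5
    return ic, ic025


def bcpnn_ic_table(table: ContingencyTable) -> Tuple[float, float]:
    ic, ic025 = bcpnn_ic(table.a, table.expected_a)
    return float(ic), float(ic025)


# ---------------------------------------------------------------------------
# vectorized forms used by the screening loop


def ror_vec(a, b, c, d):
    """Vectorized ROR: returns (estimate, lo, hi, corrected) arrays."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    corrected = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
    aa = np.where(corrected, a + 0.5, a)
    bb = np.where(corrected, b + 0.5, b)
    cc = np.where(corrected, c + 0.5, c)
    dd = np.where(corrected, d + 0.5, d)
    est = aa * dd / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return est, np.exp(np.log(est) - Z95 * se), np.exp(np.log(est) + Z95 * se), corrected


def prr_vec(a, b, c, d, yates: bool = True):
    """Vectorized PRR and chi-square."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (a / (a + b)) / (c / (c + d))
        num = np.maximum(np.abs(a * d - b * c) - (n / 2 if yates else 0.0), 0.0)
        chi2 = n * num**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return est, chi2
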