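"""Empirical-Bayes gamma-Poisson shrinkage (the multi-item gamma Poisson
shrinker, MGPS).

The observed count ``a`` of a drug-event pair is modelled as Poisson with
mean ``lambda * E``, where ``E`` is the count expected under independence
and ``lambda`` the relative reporting rate.  ``lambda`` carries a
two-component gamma mixture prior

    lambda ~ p Gamma(alpha1, beta1) + (1-p) Gamma(alpha2, beta2)

(rate parametrization), whose hyperparameters are fitted by maximizing the
marginal (negative-binomial mixture) likelihood over all pairs in the
screening universe via EM.  The per-pair posterior is again a two-gamma
mixture; EBGM is the posterior geometric mean ``2^{E[log2 lambda]}`` and
EBGM05 its 5th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats


@dataclass
class MgpsPrior:
    """Fitted hyperparameters of the two-gamma mixture prior.

    Components are ordered by prior mean (``alpha/beta``) ascending;
    ``p_mix`` is the weight of the first (low-mean) component.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    loglik: float = float("nan")
    em_iterations: int = 0
    converged: bool = True
    loglik_trace: Optional[list] = None

    def component_means(self) -> Tuple[float, float]:
        return self.alpha1 / self.beta1, self.alpha2 / self.beta2


#: box bound on log(alpha), log(beta) inside the M-step; keeps a merging
#: (near-degenerate) mixture from drifting to unbounded precision
_LOG_PARAM_BOUND = 9.0


def _nb_logpmf(a: np.ndarray, E: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # marginal of Poisson(lambda E) with lambda ~ Gamma(alpha, beta)
    return stats.nbinom.logpmf(a, alpha, beta / (beta + E))


def mixture_loglik(a: np.ndarray, E: np.ndarray, prior: MgpsPrior) -> float:
    l1 = _nb_logpmf(a, E, prior.alpha1, prior.beta1) + np.log(prior.p_mix)
    l2 = _nb_logpmf(a, E, prior.alpha2, prior.beta2) + np.log1p(-prior.p_mix)
    return float(np.logaddexp(l1, l2).sum())


def _moment_init(a: np.ndarray, E: np.ndarray) -> MgpsPrior:
    """Method-of-moments start: split the observed rate ratios at their
    median and gamma-match mean/variance within each half."""
    r = a / np.maximum(E, 1e-12)
    med = np.median(r)
    lo, hi = r[r <= med], r[r > med]
    if len(hi) == 0:  # degenerate: all ratios equal
        lo = hi = r

    def _gamma_mom(x):
        m = max(float(np.mean(x)), 1e-3)
        v = max(float(np.var(x)), 1e-3)
        return m * m / v, m / v  # alpha, beta

    a1, b1 = _gamma_mom(lo)
    a2, b2 = _gamma_mom(hi)
    return MgpsPrior(a1, b1, a2, b2, 0.5)


#: classic diffuse two-gamma start (one broad low-mean component, one
#: heavy-tailed component); complements the moment start, which can sit in
#: a merged local maximum when signals are sparse
_DIFFUSE_INIT = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _tail_init(a: np.ndarray, E: np.ndarray) -> MgpsPrior:
    """Start with the bulk in component 1 and a low-weight component 2 at
    the largest observed ratio, so EM can pick up a sparse signal tail."""
    r = a / np.maximum(E, 1e-12)
    m = max(float(np.mean(r)), 1e-3)
    v = max(float(np.var(r)), 1e-3)
    r_max = max(float(np.max(r)), m * 1.5)
    p2 = max(2.0 / len(r), 1e-3)
    return MgpsPrior(m * m / v, m / v, 2.0, 2.0 / r_max, 1.0 - p2)


def fit_prior(a: Sequence[float], E: Sequence[float], init: Optional[MgpsPrior] = None,
              tol: float = 1e-8, max_iter: int = 10_000) -> MgpsPrior:
    """Fit the mixture prior by EM on the marginal likelihood.

    Each M-step maximizes the responsibility-weighted negative-binomial
    log likelihood of one component numerically (on log-parameter scale,
    warm-started at the current values), so the marginal log likelihood is
    non-decreasing across iterations.  When no explicit ``init`` is given,
    EM is run from both a moment-based start and a diffuse start and the
    higher-likelihood optimum wins.  Non-convergence within ``max_iter``
    returns the best parameters found, flagged via ``converged=False``.
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    if init is None:
        fits = [fit_prior(a, E, init=start, tol=tol, max_iter=max_iter)
                for start in (_moment_init(a, E), _DIFFUSE_INIT, _tail_init(a, E))]
        return max(fits, key=lambda f: f.loglik)
    prior = init
    p = min(max(prior.p_mix, 1e-6), 1 - 1e-6)
    th = [prior.alpha1, prior.beta1, prior.alpha2, prior.beta2]

    def _component_nll(logab, w):
        al, be = np.exp(logab)
        ll = np.sum(w * _nb_logpmf(a, E, al, be))
        # gradient wrt (log alpha, log beta)
        g_al = np.sum(w * (special.digamma(al + a) - special.digamma(al)
                           + np.log(be / (be + E)))) * al
        g_be = np.sum(w * (al * E / (be * (be + E)) - a / (be + E))) * be
        return -float(ll), -np.array([g_al, g_be])

    ll_old = mixture_loglik(a, E, MgpsPrior(*th, p))
    trace = [ll_old]
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E-step: responsibilities of component 1
        l1 = _nb_logpmf(a, E, th[0], th[1]) + np.log(p)
        l2 = _nb_logpmf(a, E, th[2], th[3]) + np.log1p(-p)
        w1 = np.exp(l1 - np.logaddexp(l1, l2))
        # M-step
        p = min(max(float(np.mean(w1)), 1e-6), 1 - 1e-6)
        bound = (-_LOG_PARAM_BOUND, _LOG_PARAM_BOUND)
        for j, w in ((0, w1), (2, 1.0 - w1)):
            x0 = np.clip(np.log([th[j], th[j + 1]]), *bound)
            res = optimize.minimize(_component_nll, x0, args=(w,), jac=True,
                                    method="L-BFGS-B", bounds=[bound, bound])
            # keep the update only if it does not decrease the weighted lik
            if res.fun <= _component_nll(x0, w)[0]:
                th[j], th[j + 1] = np.exp(res.x)
        ll = mixture_loglik(a, E, MgpsPrior(*th, p))
        trace.append(ll)
        if abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-12):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    # order components by prior mean ascending
    if th[0] / th[1] > th[2] / th[3]:
        th = [th[2], th[3], th[0], th[1]]
        p = 1.0 - p
    return MgpsPrior(th[0], th[1], th[2], th[3], p, loglik=ll_old,
                     em_iterations=n_iter, converged=converged, loglik_trace=trace)


def posterior_weights(a, E, prior: MgpsPrior) -> Tuple[np.ndarray, np.ndarray]:
    """Updated mixture weights of the two posterior gamma components."""
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    l1 = _nb_logpmf(a, E, prior.alpha1, prior.beta1) + np.log(prior.p_mix)
    l2 = _nb_logpmf(a, E, prior.alpha2, prior.beta2) + np.log1p(-prior.p_mix)
    norm = np.logaddexp(l1, l2)
    return np.exp(l1 - norm), np.exp(l2 - norm)


def ebgm(a, E, prior: MgpsPrior) -> np.ndarray:
    """Posterior geometric mean of the relative reporting rate.

    ``exp( sum_j w_j [ psi(alpha_j + a) - ln(beta_j + E) ] )`` where the
    ``w_j`` are the posterior component weights.
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    q1, q2 = posterior_weights(a, E, prior)
    m1 = special.digamma(prior.alpha1 + a) - np.log(prior.beta1 + E)
    m2 = special.digamma(prior.alpha2 + a) - np.log(prior.beta2 + E)
    return np.exp(q1 * m1 + q2 * m2)


def posterior_cdf(x, a: float, E: float, prior: MgpsPrior) -> np.ndarray:
    q1, q2 = posterior_weights(a, E, prior)
    c1 = stats.gamma.cdf(x, prior.alpha1 + a, scale=1.0 / (prior.beta1 + E))
    c2 = stats.gamma.cdf(x, prior.alpha2 + a, scale=1.0 / (prior.beta2 + E))
    return q1 * c1 + q2 * c2


def ebgm05(a, E, prior: MgpsPrior, q: float = 0.05) -> np.ndarray:
    """Posterior 5th percentile, by monotone root-finding on the mixture CDF."""
    scalar = np.ndim(a) == 0 and np.ndim(E) == 0
    a = np.atleast_1d(np.asarray(a, dtype=float))
    E = np.atleast_1d(np.asarray(E, dtype=float))
    out = np.empty_like(a)
    for i, (ai, ei) in enumerate(zip(a, E)):
        hi = max((prior.alpha1 + ai) / (prior.beta1 + ei),
                 (prior.alpha2 + ai) / (prior.beta2 + ei)) * 20 + 10
        out[i] = optimize.brentq(lambda x: posterior_cdf(x, ai, ei, prior) - q,
                                 1e-12, hi, xtol=1e-12, rtol=1e-12)
    return float(out[0]) if scalar else out
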