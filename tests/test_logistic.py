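"""IRLS logistic regression: identities, oracle agreement, recovery."""

import numpy as np
import pandas as pd
import pytest

from pvsignal.contingency import ContingencyTable
from pvsignal.logistic import (build_design, fit_logistic_irls, or_table,
                               profile_ci, _deviance_at)
from pvsignal.records import ReportStore
from pvsignal.stats import ror
from pvsignal.synth import SyntheticConfig, generate

from conftest import TOY_VOCAB, make_record


def _fit_xy(x, y):
    X = pd.DataFrame({"(Intercept)": np.ones(len(x)), "x": np.asarray(x, float)})
    return fit_logistic_irls(X, pd.Series(y))


class TestIrls:
    def test_single_binary_covariate_equals_contingency_odds_ratio(self):
        # saturated model: logistic OR must equal ad/(bc) exactly
        a, b, c, d = 20, 80, 100, 9800
        x = np.repeat([1, 1, 0, 0], [a + b, 0, c + d, 0])
        x = np.repeat([1, 0], [a + b, c + d])
        y = np.concatenate([np.repeat([1, 0], [a, b]), np.repeat([1, 0], [c, d])])
        fit = _fit_xy(x, y)
        table_or = ror(ContingencyTable(a, b, c, d)).estimate
        assert np.exp(fit.estimates[1]) == pytest.approx(table_or, rel=1e-10)

    def test_matches_statsmodels_coefficients_and_ses(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(10)
        n = 2000
        X = pd.DataFrame({"(Intercept)": 1.0,
                          "x1": rng.normal(size=n),
                          "x2": rng.binomial(1, 0.4, n).astype(float)})
        eta = -1.0 + 0.8 * X["x1"] - 0.5 * X["x2"]
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-eta))))
        fit = fit_logistic_irls(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.estimates, ref.params.values, rtol=1e-6)
        np.testing.assert_allclose(fit.std_errors, ref.bse.values, rtol=1e-4)

    def test_deviance_non_increasing_over_newton_path(self):
        rng = np.random.default_rng(11)
        n = 500
        Xm = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 + 0.9 * Xm[:, 1]))), n).astype(float)
        beta = np.zeros(2)
        devs = [_deviance_at(Xm, y, beta)]
        for _ in range(8):
            mu = 1 / (1 + np.exp(-(Xm @ beta)))
            w = mu * (1 - mu)
            beta = beta + np.linalg.solve((Xm * w[:, None]).T @ Xm, Xm.T @ (y - mu))
            devs.append(_deviance_at(Xm, y, beta))
        assert all(d2 <= d1 + 1e-8 for d1, d2 in zip(devs, devs[1:]))

    def test_separation_flagged(self):
        x = np.repeat([0.0, 1.0], 50)
        y = np.repeat([0, 1], 50)
        fit = _fit_xy(x, y)
        assert fit.separation
        assert not fit.converged

    def test_ses_match_finite_difference_hessian(self):
        rng = np.random.default_rng(12)
        n = 1500
        X = pd.DataFrame({"(Intercept)": 1.0, "x": rng.normal(size=n)})
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.7 * X["x"])))))
        fit = fit_logistic_irls(X, y)
        Xm = X.to_numpy()
        yv = y.to_numpy(float)
        h = 1e-5
        k = 2
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                ei, ej = np.eye(k)[i] * h, np.eye(k)[j] * h
                H[i, j] = (_deviance_at(Xm, yv, fit.estimates + ei + ej)
                           - _deviance_at(Xm, yv, fit.estimates + ei - ej)
                           - _deviance_at(Xm, yv, fit.estimates - ei + ej)
                           + _deviance_at(Xm, yv, fit.estimates - ei - ej)) / (8 * h * h)
        se_fd = np.sqrt(np.diag(np.linalg.inv(H)))
        np.testing.assert_allclose(fit.std_errors, se_fd, rtol=1e-4)


class TestDesign:
    def _store(self):
        recs = [
            make_record("1", reactions=["hepatic_failure"], age_years=70,
                        weight_kg=85, sex="male"),
            make_record("2", reactions=["headache"], age_years=40,
                        weight_kg=70, sex="female"),
            make_record("3", reactions=["headache"], age_years=50,
                        weight_kg=None, sex="male"),  # dropped: missing weight
            make_record("4", reactions=["headache"], age_years=10,
                        weight_kg=110, sex="female"),
        ]
        return ReportStore.from_records(recs, TOY_VOCAB)

    def test_response_and_dummies(self):
        X, y, dropped = build_design(self._store(), ["hepatic_failure"])
        assert dropped == 1
        assert list(y) == [1, 0, 0]
        row = X.iloc[0]
        assert (row["age[>=65]"], row["weight[80-100]"], row["male"]) == (1.0, 1.0, 1.0)
        assert row["age[18-65]"] == 0.0
        row4 = X.iloc[2]
        assert (row4["age[18-65]"], row4["weight[>100]"], row4["male"]) == (0.0, 1.0, 0.0)

    def test_all_cases_or_all_controls_rejected(self):
        store = self._store()
        with pytest.raises(ValueError, match="zero cases or zero controls"):
            build_design(store, ["no_such_event"])


class TestRecovery:
    def test_planted_coefficients_recovered_within_two_ses(self):
        cfg = SyntheticConfig(n_reports=60_000, n_events=40, seed=21,
                              duplicate_rate=0.0, weight_missing=0.45,
                              target_drug_share=0.3)
        store, truth = generate(cfg)
        from pvsignal.cleaning import filter_primary_suspect
        cohort = filter_primary_suspect(store, [cfg.target_drug])
        X, y, _ = build_design(cohort, [truth.target_event])
        fit = fit_logistic_irls(X, y)
        assert fit.converged
        for term, beta_true in truth.covariate_effects.items():
            i = fit.terms.index(term)
            assert abs(fit.estimates[i] - beta_true) < 2 * fit.std_errors[i] + 0.05

    def test_or_table_shape_and_rounding(self):
        rng = np.random.default_rng(13)
        n = 4000
        X = pd.DataFrame({"(Intercept)": 1.0,
                          "x1": rng.binomial(1, 0.5, n).astype(float),
                          "x2": rng.binomial(1, 0.3, n).astype(float)})
        eta = -2.0 + 1.16 * X["x1"]
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-eta))))
        fit = fit_logistic_irls(X, y)
        table = or_table(fit)
        assert list(table["term"]) == ["(Intercept)", "x1", "x2"]
        assert table.loc[0, "or"] is None or np.isnan(table.loc[0, "or"])
        row = table.set_index("term").loc["x1"]
        assert row["or"] == pytest.approx(round(float(np.exp(fit.estimates[1])), 2))

    def test_profile_ci_brackets_mle_and_exceeds_wald_length(self):
        rng = np.random.default_rng(14)
        n = 300
        X = pd.DataFrame({"(Intercept)": 1.0, "x": rng.binomial(1, 0.5, n).astype(float)})
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-(-2.2 + 1.0 * X["x"])))))
        fit = fit_logistic_irls(X, y)
        lo, hi = profile_ci(X, y, fit, "x")
        assert lo < fit.estimates[1] < hi
        # profile intervals are asymmetric for sparse outcomes
        wald_lo = fit.estimates[1] - 1.96 * fit.std_errors[1]
        wald_hi = fit.estimates[1] + 1.96 * fit.std_errors[1]
        assert (hi - lo) > 0.8 * (wald_hi - wald_lo)
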