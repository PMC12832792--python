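"""Time-to-onset extraction, Weibull fitting, Kaplan-Meier and log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from pvsignal.records import ReportStore
from pvsignal.tto import (extract_tto, km_curve, logrank_test, summarize_tto,
                          tto_histogram, weibull_mle)

from conftest import TOY_VOCAB, make_record


def _store_with_dates(specs):
    recs = []
    for i, (start, onset) in enumerate(specs):
        recs.append(make_record(
            f"r{i}",
            therapy_start=pd.Timestamp(start) if start else None,
            event_onset=pd.Timestamp(onset) if onset else None))
    return ReportStore.from_records(recs, TOY_VOCAB)


class TestExtract:
    def test_simple_date_arithmetic(self):
        store = _store_with_dates([("2020-01-01", "2020-01-16")])
        frame, _ = extract_tto(store)
        assert list(frame["tto_days"]) == [15]

    def test_missing_onset_excluded_and_logged(self):
        store = _store_with_dates([("2020-01-01", None), ("2020-01-01", "2020-01-10")])
        frame, excl = extract_tto(store)
        assert len(frame) == 1
        assert excl["missing_dates"] == 1

    def test_same_day_onset_coded_as_one(self):
        store = _store_with_dates([("2020-01-01", "2020-01-01")])
        frame, _ = extract_tto(store)
        assert list(frame["tto_days"]) == [1]

    def test_onset_before_start_excluded(self):
        store = _store_with_dates([("2020-02-01", "2020-01-01")])
        frame, excl = extract_tto(store)
        assert len(frame) == 0
        assert excl["onset_before_start"] == 1

    def test_implausible_interval_excluded(self):
        store = _store_with_dates([("2000-01-01", "2020-01-01")])
        frame, excl = extract_tto(store)
        assert len(frame) == 0
        assert excl["implausible"] == 1


class TestSummaries:
    def test_median_of_small_sample(self):
        s = summarize_tto([1, 2, 3, 4, 5])
        assert s["median"] == 3
        assert (s["q1"], s["q3"]) == (2, 4)

    def test_single_value_degenerate(self):
        s = summarize_tto([7])
        assert s["median"] == 7
        assert s["q3"] - s["q1"] == 0

    def test_weibull_sample_median_matches_closed_form(self):
        rng = np.random.default_rng(42)
        beta, alpha = 0.67, 37.64
        t = alpha * rng.weibull(beta, 10_000)
        expected = alpha * np.log(2) ** (1 / beta)  # ~ 21.7 days
        assert expected == pytest.approx(21.7, abs=0.1)
        assert summarize_tto(t)["median"] == pytest.approx(expected, rel=0.05)


class TestWeibullMle:
    def test_exponential_data_recovers_shape_one(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(30.0, 5000)
        fit = weibull_mle(t)
        assert fit.shape_beta == pytest.approx(1.0, abs=0.04)
        assert fit.failure_type == "random"

    def test_matches_independent_numerical_maximizer(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            beta = rng.uniform(0.4, 3.0)
            alpha = rng.uniform(5, 100)
            t = alpha * rng.weibull(beta, 400)
            fit = weibull_mle(t)
            # scipy's generic MLE of the same two-parameter family
            shape_sp, _, scale_sp = sstats.weibull_min.fit(t, floc=0)
            assert fit.shape_beta == pytest.approx(shape_sp, rel=1e-4)
            assert fit.scale_alpha == pytest.approx(scale_sp, rel=1e-4)

    def test_early_failure_classification(self):
        rng = np.random.default_rng(3)
        t = 37.6 * rng.weibull(0.67, 3000)
        fit = weibull_mle(t)
        assert fit.ci95_beta[1] < 1.0
        assert fit.failure_type == "early"

    def test_wear_out_classification(self):
        rng = np.random.default_rng(4)
        t = 30.0 * rng.weibull(1.6, 2000)
        assert weibull_mle(t).failure_type == "wear_out"

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            weibull_mle([5.0] * 50)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            weibull_mle([1, 2, 3])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_curve([2, 2, 5])
        surv = dict(zip(curve.times, curve.survival))
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[5.0] == pytest.approx(0.0)

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(5)
        t = rng.integers(1, 50, 200).astype(float)
        curve = km_curve(t)
        for u, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((t > u).mean(), abs=1e-12)

    def test_survival_non_increasing_from_one(self):
        curve = km_curve([3, 1, 4, 1, 5, 9, 2, 6])
        assert curve.survival[0] <= 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve([])


def _logrank_oracle(groups):
    """Brute-force observed-minus-expected log-rank for k groups, all events."""
    all_t = np.concatenate(list(groups.values()))
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    names = list(groups)
    times = np.unique(all_t)
    O = np.zeros(len(names))
    Eexp = np.zeros(len(names))
    Vdiag = np.zeros(len(names))
    for u in times:
        at_risk = all_t >= u
        events = all_t == u
        n_u = at_risk.sum()
        d_u = events.sum()
        for i, name in enumerate(names):
            n_i = (at_risk & (labels == name)).sum()
            O[i] += (events & (labels == name)).sum()
            Eexp[i] += d_u * n_i / n_u
            if n_u > 1:
                Vdiag[i] += d_u * (n_i / n_u) * (1 - n_i / n_u) * (n_u - d_u) / (n_u - 1)
    # two-group shortcut: (O1-E1)^2 / V1
    return (O[0] - Eexp[0]) ** 2 / Vdiag[0]


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        res = logrank_test({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_six_observation_worked_example_matches_oracle(self):
        groups = {"a": np.array([1.0, 3.0, 5.0]), "b": np.array([2.0, 4.0, 6.0])}
        res = logrank_test(groups)
        assert res.df == 1
        assert res.chi2 == pytest.approx(_logrank_oracle(groups), rel=1e-6)

    def test_tied_event_times_match_oracle(self):
        groups = {"a": np.array([2.0, 2.0, 4.0, 7.0]), "b": np.array([2.0, 5.0, 5.0, 9.0])}
        res = logrank_test(groups)
        assert res.chi2 == pytest.approx(_logrank_oracle(groups), rel=1e-6)

    def test_three_groups_two_degrees_of_freedom(self):
        res = logrank_test({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert res.df == 2

    def test_invariant_under_common_time_rescaling(self):
        rng = np.random.default_rng(6)
        g = {"a": rng.exponential(10, 40), "b": rng.exponential(15, 40)}
        r1 = logrank_test(g)
        r2 = logrank_test({k: 3.0 * v for k, v in g.items()})
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-9)
        assert r1.chi2 >= 0


class TestHistogram:
    def test_all_in_first_bin(self):
        h = tto_histogram([10] * 7)
        assert h.loc[0, "count"] == 7
        assert h.loc[0, "proportion"] == 1.0

    def test_right_edge_inclusive(self):
        h = tto_histogram([30, 31])
        assert h.loc[0, "count"] == 1  # 30 belongs to 1-30
        assert h.loc[1, "count"] == 1  # 31 belongs to 31-60

    def test_proportions_sum_to_one_and_early_failure_peaks_first(self):
        rng = np.random.default_rng(7)
        t = np.maximum(1, np.ceil(37.6 * rng.weibull(0.67, 5000)))
        h = tto_histogram(t)
        assert h["proportion"].sum() == pytest.approx(1.0)
        assert h["count"].idxmax() == 0
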