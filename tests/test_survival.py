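import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from crowdscore.survival import (
    cox_fit,
    km_estimate,
    logrank_test,
    median_split,
    split_quartiles,
    subgroup_analysis,
)


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        km = km_estimate([3.0, 5.0, 8.0], [False, False, False])
        assert (km["survival"] == 1.0).all()

    def test_three_records_all_events(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km["at_risk"], [3, 2, 1])

    def test_six_records_mixed_censoring(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, False, True, True, False, True]
        km = km_estimate(times, events).set_index("time")
        assert km.loc[1.0, "survival"] == pytest.approx(5 / 6)
        assert km.loc[2.0, "survival"] == pytest.approx(5 / 6)
        assert km.loc[3.0, "survival"] == pytest.approx(5 / 6 * 3 / 4)
        assert km.loc[4.0, "survival"] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert km.loc[6.0, "survival"] == pytest.approx(0.0)

    def test_duplication_invariance(self):
        t = [2.0, 4.0, 7.0, 9.0]
        e = [True, False, True, True]
        a = km_estimate(t, e)
        b = km_estimate(t * 2, e * 2)
        np.testing.assert_allclose(a["survival"], b["survival"])

    def test_product_limit_formula_oracle(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40).round(1) + 0.1
        e = rng.random(40) < 0.7
        km = km_estimate(t, e)
        # direct product over event times of (1 - d_i / n_i)
        surv = 1.0
        expected_last = None
        for time in sorted(set(t)):
            n_at_risk = (t >= time).sum()
            d = ((t == time) & e).sum()
            if d:
                surv *= 1 - d / n_at_risk
            expected_last = surv
        assert km["survival"].iloc[-1] == pytest.approx(expected_last)
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])


def logrank_oracle(times, events, group):
    """Direct observed-minus-expected computation, 1 df."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    g = np.asarray(group)
    labels = np.unique(g)
    u = v = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (g == labels[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (g == labels[0])).sum()
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u**2 / v


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        t = [1.0, 3.0, 5.0, 7.0]
        e = [True, True, False, True]
        stat, p = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 60) + 0.01
        g = np.repeat(["a", "b"], 30)
        t[g == "b"] *= 0.5
        e = rng.random(60) < 0.8
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(logrank_oracle(t, e, g), rel=1e-9)

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(3)
        n = 100
        g = np.repeat(["lo", "hi"], n)
        t = np.concatenate(
            [rng.exponential(50, n), rng.exponential(10, n)]
        )
        _, p = logrank_test(t, np.ones(2 * n, bool), g)
        assert p < 1e-3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [True, True], ["a", "a"])
        with pytest.raises(ValueError):
            logrank_test([1, 2, 3], [True, True, False],
                         ["a", "a", "b"])


def partial_likelihood(beta, x, times, events):
    """Breslow log partial likelihood for a single covariate, no ties."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestCox:
    def _hand_data(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([True, True, False, True, True, True])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        return times, events, x

    def test_single_covariate_matches_likelihood_scan_oracle(self):
        times, events, x = self._hand_data()
        res = cox_fit(pd.DataFrame({"x": x}), times, events)
        opt = minimize_scalar(
            lambda b: -partial_likelihood(b, x, times, events),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.coef[0] == pytest.approx(opt.x, abs=1e-5)

    def test_optimum_beats_null(self):
        times, events, x = self._hand_data()
        res = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert partial_likelihood(res.coef[0], x, times, events) >= (
            partial_likelihood(0.0, x, times, events)
        )

    def test_hr_is_exp_coef_and_ci_ordering(self):
        times, events, x = self._hand_data()
        res = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert res.hazard_ratio[0] == pytest.approx(np.exp(res.coef[0]))
        assert res.ci_low[0] < res.hazard_ratio[0] < res.ci_high[0]
        assert res.n == 6 and res.n_events == 5

    def test_noise_covariate_leaves_signal_within_one_se(self):
        rng = np.random.default_rng(4)
        n = 1500
        h = rng.uniform(0, 300, n)
        t = rng.exponential(1.0 / (0.02 * np.exp(-0.008 * h)))
        c = rng.exponential(200, n)
        times, events = np.minimum(t, c), t <= c
        base = cox_fit(pd.DataFrame({"h": h}), times, events)
        noise = rng.normal(size=n)
        multi = cox_fit(pd.DataFrame({"h": h, "z": noise}), times, events)
        se = (np.log(base.ci_high[0]) - np.log(base.ci_low[0])) / (2 * 1.96)
        assert abs(multi.coef[0] - base.coef[0]) < se

    def test_preconditions(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, True, False])
        with pytest.raises(ValueError):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}), times, events)
        with pytest.raises(ValueError):
            cox_fit(
                pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [4.0, 3, 2, 1],
                              "z": [1.0, 3, 2, 4]}),
                times,
                np.array([True, True, False, False]),
            )


class TestSplits:
    def test_quartiles_one_to_eight(self):
        labels = split_quartiles(np.arange(1.0, 9.0))
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_all_equal_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = split_quartiles(np.full(10, 7.0))
        assert (labels == 1).all()

    def test_too_few(self):
        with pytest.raises(ValueError):
            split_quartiles([1.0, 2.0, 3.0])

    def test_ties_go_low(self):
        labels = split_quartiles([1.0, 1, 1, 1, 2, 2, 2, 2])
        assert set(labels[:4]) == {1}

    def test_median_split_basic(self):
        np.testing.assert_array_equal(
            median_split([1.0, 2.0, 3.0]), ["low", "low", "high"]
        )

    def test_median_split_balance_and_translation(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=40)
        labels = median_split(v)
        n_high = (labels == "high").sum()
        assert abs(n_high - 20) <= 1
        np.testing.assert_array_equal(labels, median_split(v + 100.0))

    def test_median_split_too_few(self):
        with pytest.raises(ValueError):
            median_split([1.0])


class TestSubgroup:
    def _patients(self, n, seed, beta_high_only=False):
        rng = np.random.default_rng(seed)
        strat = rng.uniform(0, 300, n)
        analyte = rng.uniform(0, 300, n)
        beta = -0.008
        if beta_high_only:
            active = strat > np.median(strat)
            rate = 0.02 * np.exp(beta * analyte * active)
        else:
            rate = 0.02 * np.exp(beta * analyte)
        t = rng.exponential(1.0 / rate)
        c = rng.exponential(150, n)
        patients = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "time_months": np.minimum(t, c),
                "event": t <= c,
            }
        )
        scores = pd.concat(
            [
                pd.DataFrame({"patient_id": patients["patient_id"],
                              "marker_id": "S", "h_score": strat}),
                pd.DataFrame({"patient_id": patients["patient_id"],
                              "marker_id": "A", "h_score": analyte}),
            ]
        )
        return patients, scores

    def test_independent_stratifier_recovers_global_hr(self):
        patients, scores = self._patients(1200, seed=6)
        res = subgroup_analysis(patients, scores, "S", "A")
        for stratum in ("low", "high"):
            hr = res[stratum].hazard_ratio[0]
            assert res[stratum].ci_low[0] < np.exp(-0.008) < res[stratum].ci_high[0]
            assert 0.985 < hr < 0.999

    def test_effect_detected_only_in_active_stratum(self):
        patients, scores = self._patients(1000, seed=7, beta_high_only=True)
        res = subgroup_analysis(patients, scores, "S", "A")
        assert res["high"].p_value[0] < 0.01
        assert res["low"].ci_low[0] < 1.0 < res["low"].ci_high[0]

    def test_constant_stratifier_rejected(self):
        patients, scores = self._patients(100, seed=8)
        scores.loc[scores["marker_id"] == "S", "h_score"] = 50.0
        with pytest.raises(ValueError):
            subgroup_analysis(patients, scores, "S", "A")

    def test_missing_marker_rejected(self):
        patients, scores = self._patients(100, seed=9)
        with pytest.raises(ValueError):
            subgroup_analysis(patients, scores, "S", "missing")
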