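import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lohcna.survival_analysis import (
    bivariate_scan,
    cox_fit,
    km_estimate,
    logrank_test,
    stratified_km_report,
)


def logrank_statistic(time, event, group) -> float:
    """Independent closed-form two-group log-rank chi-square (no ties assumed
    beyond shared event times; standard hypergeometric variance)."""
    time, event, group = map(np.asarray, (time, event, group))
    stat_num = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        stat_num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return stat_num**2 / var


def simulate(rng, n, hr, censor_scale=None):
    flag = rng.random(n) < 0.5
    lam = 0.02 * np.where(flag, hr, 1.0)
    t = rng.exponential(1 / lam)
    if censor_scale is None:
        return pd.DataFrame({"time": t, "event": 1, "flag": flag.astype(int)})
    c = rng.exponential(censor_scale, size=n)
    return pd.DataFrame(
        {"time": np.minimum(t, c), "event": (t <= c).astype(int), "flag": flag.astype(int)}
    )


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = km_estimate([5, 8, 12], [0, 0, 0])
        assert (km.survival == 1.0).all() and np.isinf(km.median)

    def test_three_events_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 2, 1]

    def test_median_is_first_time_at_or_below_half(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.median == 2  # S(2) = 0.5

    def test_censoring_reduces_risk_set_only(self):
        # hand product-limit: events at 2 and 5, censoring at 3
        km = km_estimate([2, 3, 5], [1, 0, 1])
        assert km.survival_at(2) == pytest.approx(2 / 3)
        assert km.survival_at(5) == pytest.approx(2 / 3 * (1 - 1 / 1))

    def test_event_before_censoring_at_tied_time(self):
        km = km_estimate([2, 2], [1, 0])
        assert km.survival_at(2) == pytest.approx(0.5)


class TestLogrank:
    def test_identical_groups(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        assert logrank_test(t, e, t, e) == pytest.approx(1.0)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            logrank_test([1, 2], [0, 0], [3], [0])

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(10, 20), rng.exponential(20, 25)
        ea = np.ones(20, int)
        eb = (rng.random(25) < 0.8).astype(int)
        assert logrank_test(ta, ea, tb, eb) == pytest.approx(
            logrank_test(tb, eb, ta, ea)
        )

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        ta = rng.uniform(1, 10, 30)       # early events
        tb = rng.uniform(8, 30, 30)       # late events
        time = np.concatenate([ta, tb])
        event = np.ones(60, int)
        group = np.array([1] * 30 + [0] * 30)
        p_pkg = logrank_test(ta, np.ones(30, int), tb, np.ones(30, int))
        obs = logrank_statistic(time, event, group)
        g = group.copy()
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(g)
            if logrank_statistic(time, event, g) >= obs:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        # both are tiny for strongly separated groups; agree within MC resolution
        assert p_pkg < 1e-3 and p_perm < 1e-3

    def test_moderate_difference_matches_permutation(self):
        rng = np.random.default_rng(3)
        ta = rng.exponential(10, 25)
        tb = rng.exponential(16, 25)
        time = np.concatenate([ta, tb])
        event = np.ones(50, int)
        group = np.array([1] * 25 + [0] * 25)
        p_pkg = logrank_test(ta, np.ones(25, int), tb, np.ones(25, int))
        obs = logrank_statistic(time, event, group)
        g = group.copy()
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(g)
            if logrank_statistic(time, event, g) >= obs:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert p_pkg == pytest.approx(
            p_perm, abs=max(0.02, 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm))
        )

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(500):
            t = rng.exponential(10, 40)
            e = np.ones(40, int)
            ps.append(logrank_test(t[:20], e[:20], t[20:], e[20:]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCox:
    def test_null_covariate_ci_contains_one(self):
        df = simulate(np.random.default_rng(5), 500, hr=1.0, censor_scale=80)
        fit = cox_fit(df, ["flag"])
        row = fit.summary.loc["flag"]
        assert row.ci_lower < 1 < row.ci_upper

    def test_planted_hazard_ratio_recovered(self):
        df = simulate(np.random.default_rng(6), 2000, hr=0.65, censor_scale=120)
        fit = cox_fit(df, ["flag"])
        assert 0.55 <= fit.hr("flag") <= 0.77
        assert fit.summary.loc["flag", "ci_lower"] <= fit.hr("flag") <= fit.summary.loc["flag", "ci_upper"]

    def test_noise_covariate_leaves_planted_effect_stable(self):
        rng = np.random.default_rng(7)
        df = simulate(rng, 1500, hr=0.65, censor_scale=120)
        df["noise"] = rng.normal(size=len(df))
        uni = cox_fit(df, ["flag"])
        multi = cox_fit(df, ["flag", "noise"])
        lo, hi = uni.summary.loc["flag", ["ci_lower", "ci_upper"]]
        assert lo <= multi.hr("flag") <= hi

    def test_constant_covariate_rejected(self):
        df = simulate(np.random.default_rng(8), 50, hr=1.0)
        df["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["const"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "flag": [0, 1]})
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["flag"])

    def test_parameter_recovery_and_ci_coverage(self):
        # repeated-cohort check: mean estimate near truth, Wald CI calibrated
        rng = np.random.default_rng(9)
        beta = np.log(0.65)
        betas, covered = [], 0
        n_rep = 150
        for _ in range(n_rep):
            df = simulate(rng, 300, hr=0.65)
            fit = cox_fit(df, ["flag"])
            betas.append(float(fit.summary.loc["flag", "coef"]))
            lo, hi = fit.summary.loc["flag", ["ci_lower", "ci_upper"]]
            covered += np.log(lo) <= beta <= np.log(hi)
        assert np.mean(betas) == pytest.approx(beta, abs=0.05)
        assert 0.90 <= covered / n_rep <= 0.98


class TestBivariateScan:
    def test_empty_covariate_list(self):
        df = simulate(np.random.default_rng(10), 100, hr=0.8)
        assert bivariate_scan(df, "flag", []).empty

    def test_duplicate_of_fixed_rejected(self):
        df = simulate(np.random.default_rng(11), 100, hr=0.8)
        df["copy"] = df["flag"]
        with pytest.raises(ValueError, match="collinear|identical"):
            bivariate_scan(df, "flag", ["copy"])

    def test_fixed_effect_stable_across_confounders(self):
        rng = np.random.default_rng(12)
        df = simulate(rng, 1200, hr=0.65, censor_scale=120)
        # correlated with the flag, but carries no hazard of its own
        df["confounder"] = df["flag"] * 0.6 + rng.normal(0, 1, len(df))
        df["noise"] = rng.normal(size=len(df))
        uni = cox_fit(df, ["flag"])
        scan = bivariate_scan(df, "flag", ["confounder", "noise"])
        lo, hi = uni.summary.loc["flag", ["ci_lower", "ci_upper"]]
        assert ((scan.hr >= lo) & (scan.hr <= hi)).all()


class TestStratifiedKM:
    def test_two_identical_strata(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        strata = list("aaaabbbb")
        _, global_p, pairs = stratified_km_report(time, event, strata)
        assert global_p == pytest.approx(1.0)
        assert pairs.p_value.iloc[0] == pytest.approx(1.0)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError, match="two strata"):
            stratified_km_report([1, 2], [1, 1], ["a", "a"])

    def test_ordered_hazards_give_ordered_medians(self):
        rng = np.random.default_rng(13)
        rates = {"mut_loh": 0.005, "wt_loh": 0.01, "wt_noloh": 0.02, "mut_noloh": 0.04}
        time, event, strata = [], [], []
        for lab, lam in rates.items():
            t = rng.exponential(1 / lam, 150)
            time.extend(t)
            event.extend([1] * 150)
            strata.extend([lab] * 150)
        curves, global_p, _ = stratified_km_report(time, event, strata)
        medians = [curves[lab].median for lab in rates]
        assert medians == sorted(medians, reverse=True)
        assert global_p < 1e-6
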