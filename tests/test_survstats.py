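"""Survival battery: KM/log-rank, Cox vs an Efron oracle, competing risks,
group comparisons and AUC screening."""

import numpy as np
import pandas as pd
import pytest

from compoct.survstats import (
    auc_screen,
    compare_groups,
    cox_fit,
    cumulative_incidence,
    gray_test,
    km_logrank,
)


def _table(times, events, group, endpoint="os"):
    return pd.DataFrame({
        f"{endpoint}_time_months": times,
        f"{endpoint}_event": events,
        "grp": group,
    })


class TestKaplanMeier:
    def test_no_events_all_curves_at_one(self):
        t = _table([5, 6, 7, 8], [0, 0, 0, 0], [0, 0, 1, 1])
        fit = km_logrank(t, "grp", "os")
        for lev in (0, 1):
            assert fit.survival_at(lev, 100.0) == 1.0
        assert fit.logrank_p == 1.0

    def test_single_death_product_limit(self):
        t = _table([2, 3, 4, 5, 6, 9, 9], [1, 0, 0, 0, 0, 0, 0],
                   [0, 0, 0, 0, 0, 1, 1])
        fit = km_logrank(t, "grp", "os")
        assert fit.survival_at(0, 2.0) == pytest.approx(0.8)
        assert fit.survival_at(0, 1.9) == 1.0  # right continuity

    def test_curve_monotone_starts_at_one(self):
        rng = np.random.default_rng(0)
        t = _table(rng.exponential(10, 100), rng.integers(0, 2, 100),
                   rng.integers(0, 2, 100))
        fit = km_logrank(t, "grp", "os")
        for lev in (0, 1):
            s = fit.curves[lev]["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert (np.diff(s) <= 1e-12).all()
            assert fit.survival_at(lev, 0.0) == 1.0

    def test_single_level_group_rejected(self):
        t = _table([1, 2, 3], [1, 1, 0], [0, 0, 0])
        with pytest.raises(ValueError, match="single level"):
            km_logrank(t, "grp", "os")

    def test_nonpositive_times_rejected(self):
        t = _table([0.0, 2, 3], [1, 1, 0], [0, 1, 1])
        with pytest.raises(ValueError, match="positive"):
            km_logrank(t, "grp", "os")

    def test_logrank_type_I_error(self):
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            times = rng.exponential(20.0, 60)
            censor = rng.uniform(5.0, 40.0, 60)
            t = _table(np.minimum(times, censor),
                       (times <= censor).astype(int),
                       np.repeat([0, 1], 30))
            if km_logrank(t, "grp", "os").logrank_p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestCox:
    def test_null_recovery_large_n(self):
        rng = np.random.default_rng(1)
        n = 2000
        g = np.repeat([0, 1], n // 2)
        times = rng.exponential(10.0, n)
        censor = rng.uniform(5, 30, n)
        t = _table(np.minimum(times, censor), (times <= censor).astype(int), g)
        t["x"] = g
        fit = cox_fit(t, ["x"], "os")
        assert 0.9 <= fit.effects["x"].hr <= 1.1
        assert fit.model_type == "univariate"

    def test_matches_efron_grid_oracle(self):
        # tied events exercise the Efron correction
        t = _table([1.0, 1.0, 2.0, 3.0], [1, 1, 1, 0], [0, 0, 0, 0])
        t["x"] = [1.0, 0.0, 1.0, 0.0]

        def efron_loglik(b):
            # t=1: 2 tied events (x=1, x=0); risk set has x = 1,0,1,0
            s_risk = 2 * np.exp(b) + 2
            s_tied = np.exp(b) + 1
            ll = b * 1.0
            ll -= np.log(s_risk) + np.log(s_risk - 0.5 * s_tied)
            # t=2: one event (x=1); risk set x = 1,0
            ll += b - np.log(np.exp(b) + 1)
            return ll

        grid = np.linspace(-3, 3, 60001)
        oracle = grid[np.argmax([efron_loglik(b) for b in grid])]
        fit = cox_fit(t, ["x"], "os")
        assert np.log(fit.effects["x"].hr) == pytest.approx(oracle, abs=1e-3)

    def test_recovers_simulated_hazard_ratio(self):
        from compoct.cohortsim import CohortSpec, cohort_to_table, simulate_cohort

        logs = []
        for seed in range(25):
            spec = CohortSpec(seed=seed, hr_os={"hypodense": 2.80},
                              hr_pfs={"hypodense": 2.22})
            table = cohort_to_table(simulate_cohort(spec))
            logs.append(np.log(cox_fit(table, ["hypodense"], "os")
                               .effects["hypodense"].hr))
        assert abs(np.mean(logs) - np.log(2.80)) < 0.1

    def test_no_events_rejected(self):
        t = _table([1, 2, 3, 4], [0, 0, 0, 0], [0, 1, 0, 1])
        t["x"] = [0.0, 1.0, 0.0, 1.0]
        with pytest.raises(ValueError, match="no events"):
            cox_fit(t, ["x"], "os")

    def test_separation_raises(self):
        # the covariate perfectly orders events before censorings
        t = _table([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0],
                   [0, 0, 0, 1, 1, 1])
        t["x"] = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        with pytest.raises(RuntimeError, match="converge"):
            cox_fit(t, ["x"], "os")


def _competing_table(seed=0, n=200, lam=0.04, p_nrm=0.3):
    rng = np.random.default_rng(seed)
    g = np.repeat([0, 1], n // 2)
    times = rng.exponential(1 / lam, n)
    cause = np.where(rng.uniform(size=n) < p_nrm, "nrm", "relapse")
    censor = rng.uniform(5, 60, n)
    event = times <= censor
    return pd.DataFrame({
        "pfs_time_months": np.minimum(times, censor),
        "failure_cause": np.where(event, cause, "censored"),
        "grp": g,
    })


class TestCumulativeIncidence:
    def test_single_cause_reduces_to_km(self):
        from lifelines import KaplanMeierFitter

        t = _competing_table(seed=3, p_nrm=0.0)
        cif = cumulative_incidence(t, "grp", causes=("relapse", "nrm"))
        sub = t[t.grp == 0]
        kmf = KaplanMeierFitter()
        kmf.fit(sub.pfs_time_months, sub.failure_cause == "relapse")
        for tt in (5.0, 15.0, 30.0):
            assert cif.cif_at(0, "relapse", tt) == pytest.approx(
                1.0 - float(kmf.predict(tt)), abs=1e-9)
            assert cif.cif_at(0, "nrm", tt) == 0.0

    def test_conservation_identity(self):
        from lifelines import KaplanMeierFitter

        t = _competing_table(seed=4)
        cif = cumulative_incidence(t, "grp")
        sub = t[t.grp == 1]
        kmf = KaplanMeierFitter()
        kmf.fit(sub.pfs_time_months, sub.failure_cause != "censored")
        for tt in (5.0, 12.0, 25.0, 40.0):
            total = (cif.cif_at(1, "relapse", tt) + cif.cif_at(1, "nrm", tt)
                     + float(kmf.predict(tt)))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_cif_monotone_and_bounded(self):
        t = _competing_table(seed=5)
        cif = cumulative_incidence(t, "grp")
        for key, df in cif.curves.items():
            v = df["cif"].to_numpy()
            assert (np.diff(v) >= -1e-12).all()
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_unknown_cause_rejected(self):
        t = _competing_table(seed=6)
        t.loc[0, "failure_cause"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            cumulative_incidence(t, "grp")


class TestGray:
    def test_matches_R_cmprsk_two_groups(self):
        """Frozen oracle: R cmprsk::cuminc on this exact fixture gives
        chi2 = 1.153523 (cause 1) and 4.229771 (cause 2)."""
        rng = np.random.default_rng(42)
        n = 120
        g = rng.integers(0, 2, n)
        lam = np.where(g == 1, 0.04, 0.02)
        t = rng.exponential(1 / lam)
        cause = np.where(
            rng.uniform(size=n) < np.where(g == 1, 0.5, 0.25), 2, 1)
        c = rng.uniform(5, 40, n)
        ev = np.where(t <= c, cause, 0)
        time = np.minimum(t, c)
        chi2_1, _ = gray_test(time, ev, g, cause_code=1)
        chi2_2, _ = gray_test(time, ev, g, cause_code=2)
        assert chi2_1 == pytest.approx(1.153523, rel=0.05)
        assert chi2_2 == pytest.approx(4.229771, rel=0.05)

    def test_matches_R_cmprsk_three_groups_ties(self):
        """Frozen oracle: cmprsk gives 0.0676982 / 3.683256 on this
        tied, three-group fixture."""
        rng = np.random.default_rng(7)
        n = 90
        g = rng.integers(0, 3, n)
        t = np.ceil(rng.exponential(np.where(g == 2, 15, 25), n))
        cause = rng.integers(1, 3, n)
        c = np.ceil(rng.uniform(5, 30, n))
        ev = np.where(t <= c, cause, 0)
        time = np.minimum(t, c)
        chi2_1, _ = gray_test(time, ev, g, cause_code=1)
        chi2_2, _ = gray_test(time, ev, g, cause_code=2)
        assert chi2_1 == pytest.approx(0.0676982, rel=0.15, abs=0.02)
        assert chi2_2 == pytest.approx(3.683256, rel=0.15)

    def test_strong_difference_detected(self):
        rng = np.random.default_rng(9)
        n = 400
        g = np.repeat([0, 1], n // 2)
        lam = np.where(g == 1, 0.08, 0.01)
        t = np.minimum(rng.exponential(1 / lam), 40.0)
        ev = np.where(t < 40.0, 1, 0)
        _, p = gray_test(t, ev, g, cause_code=1)
        assert p < 1e-6


class TestCompare:
    def test_reference_mortality_proportions(self):
        rows = ([{"hypodense": 1, "died": 1}] * 15
                + [{"hypodense": 1, "died": 0}] * 50
                + [{"hypodense": 0, "died": 1}] * 58
                + [{"hypodense": 0, "died": 0}] * 533)
        r = compare_groups(pd.DataFrame(rows), "died", "hypodense")
        assert r.test == "chi2"
        assert round(100 * r.proportions[1], 1) == 23.1
        assert round(100 * r.proportions[0], 1) == 9.8
        assert r.p < 0.01

    def test_identical_groups_chi2_p_one(self):
        rows = ([{"g": 0, "x": 0}] * 20 + [{"g": 0, "x": 1}] * 10
                + [{"g": 1, "x": 0}] * 20 + [{"g": 1, "x": 1}] * 10)
        r = compare_groups(pd.DataFrame(rows), "x", "g")
        assert r.statistic == 0.0
        assert r.p == 1.0

    def test_continuous_uses_t(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"v": rng.normal(size=40),
                          "g": np.repeat([0, 1], 20)})
        r = compare_groups(t, "v", "g")
        assert r.test == "t"
        assert r.means is not None

    def test_t_type_I_error(self):
        rng = np.random.default_rng(321)
        n_rep, rejections = 1000, 0
        for _ in range(n_rep):
            t = pd.DataFrame({"v": rng.normal(size=40),
                              "g": np.repeat([0, 1], 20)})
            if compare_groups(t, "v", "g").p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_sparse_table_warns(self):
        # min expected cell = 2*1/5 = 0.4 < 1
        rows = ([{"g": 0, "x": 0}] * 3 + [{"g": 1, "x": 0}] * 1
                + [{"g": 1, "x": 1}] * 1)
        r = compare_groups(pd.DataFrame(rows), "x", "g")
        assert r.warning is not None


class TestAUC:
    def test_perfect_separation(self):
        t = pd.DataFrame({"x": [1, 2, 3, 10, 11, 12],
                          "y": [0, 0, 0, 1, 1, 1]})
        auc, retained = auc_screen(t, "x", "y")
        assert auc == 1.0 and retained

    def test_independent_variable_near_half(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"x": rng.normal(size=4000),
                          "y": rng.integers(0, 2, 4000)})
        auc, retained = auc_screen(t, "x", "y")
        assert abs(auc - 0.5) < 0.03 and not retained

    def test_equals_mann_whitney_pair_count(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0],
                          "y": [0, 0, 1, 0, 1, 1]})
        pos = t[t.y == 1].x.to_numpy()
        neg = t[t.y == 0].x.to_numpy()
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        auc, _ = auc_screen(t, "x", "y")
        assert auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_one_class_rejected(self):
        t = pd.DataFrame({"x": [1, 2, 3], "y": [1, 1, 1]})
        with pytest.raises(ValueError):
            auc_screen(t, "x", "y")


def test_logrank_close_to_cox_score_p():
    """Log-rank p and the single-covariate Cox p agree on a binary group."""
    from compoct.cohortsim import CohortSpec, cohort_to_table, simulate_cohort

    spec = CohortSpec(seed=2, hr_os={"hypodense": 1.8},
                      hr_pfs={"hypodense": 1.8})
    t = cohort_to_table(simulate_cohort(spec))
    km = km_logrank(t, "hypodense", "os")
    cox = cox_fit(t, ["hypodense"], "os")
    lp, cp = km.logrank_p, cox.effects["hypodense"].p
    assert abs(np.log(lp) - np.log(cp)) < 0.35  # same order, close p
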