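"""Statistics: test selection, log-rank, Cox, matching, power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats as sps

from umevo import (CoxConvergenceError, association_scan, categorical_test,
                   cox_fit, km_logrank, logrank_power, logrank_two_group,
                   propensity_match, schoenfeld_power, select_test,
                   survival_at_times)
from umevo.stats import expected_counts


class TestSelectTest:
    def test_expected_counts_formula(self):
        exp = expected_counts([[10, 20], [30, 40]])
        assert exp[0, 0] == pytest.approx(30 * 40 / 100)

    def test_large_balanced_table_is_chi_square(self):
        assert select_test([[30, 30], [30, 30]]) == "chi_square"

    def test_sparse_table_is_fisher(self):
        assert select_test([[2, 3], [1, 4]]) == "fisher"

    def test_quarter_rule_boundary(self):
        # exactly 25% of cells below 5 -> fisher (rule is inclusive)
        t = [[2, 40], [8, 40]]
        exp = expected_counts(t)
        assert (exp < 5).mean() == pytest.approx(0.25)
        assert select_test(t) == "fisher"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            select_test([[0, 0], [0, 0]])

    def test_selection_matches_direct_computation_random_tables(self, rng):
        for _ in range(1000):
            t = rng.integers(0, 30, size=(2, 2))
            if t.sum() == 0:
                continue
            exp = expected_counts(t)
            want = "fisher" if (exp < 5).mean() >= 0.25 else "chi_square"
            assert select_test(t) == want


class TestCategoricalTest:
    def test_fisher_2x2_matches_scipy(self):
        t = [[8, 2], [1, 9]]
        used, stat, p = categorical_test(t)
        assert used == "fisher"
        assert p == pytest.approx(sps.fisher_exact(t)[1], rel=1e-12)
        assert p == pytest.approx(0.005477, abs=5e-4)

    def test_chi_square_no_continuity_correction(self):
        t = [[30, 20], [20, 30]]
        used, stat, p = categorical_test(t)
        assert used == "chi_square"
        s, pref, _, _ = sps.chi2_contingency(t, correction=False)
        assert stat == pytest.approx(s) and p == pytest.approx(pref)

    def test_rxc_fisher_mc_is_seeded_and_sane(self):
        t = [[4, 0, 1], [0, 4, 0], [1, 0, 4]]
        used, _, p1 = categorical_test(t, seed=7)
        _, _, p2 = categorical_test(t, seed=7)
        assert used == "fisher" and p1 == p2
        # strong diagonal structure: association should be detected
        assert p1 < 0.05


class TestAssociationScan:
    def _frame(self, rng, n=120):
        mut = rng.random(n) < 0.4
        return pd.DataFrame({
            "mut": mut,
            "stage": np.where(mut, rng.choice(["II", "III"], n, p=[0.2, 0.8]),
                              rng.choice(["II", "III"], n, p=[0.8, 0.2])),
            "diameter_mm": rng.normal(12 + 4 * mut, 2),
            "flat": np.ones(n)})

    def test_detects_planted_associations(self, rng):
        res = {r.variable: r for r in association_scan(
            self._frame(rng), "mut",
            {"stage": "categorical", "diameter_mm": "continuous"}, seed=1)}
        assert res["stage"].p_value < 1e-4
        assert res["diameter_mm"].p_value < 1e-4
        assert res["diameter_mm"].test_used == "wilcoxon"

    def test_constant_variable_untestable(self, rng):
        res = association_scan(self._frame(rng), "mut", {"flat": "continuous"})
        assert res[0].untestable and res[0].p_value is None

    def test_constant_mutation_untestable(self, rng):
        df = self._frame(rng).assign(mut=True)
        res = association_scan(df, "mut", {"stage": "categorical"})
        assert res[0].untestable

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            association_scan(self._frame(rng), "mut", {"stage": "ordinal"})


def permutation_logrank_p(time, event, group, statistic_fn):
    """Exact permutation distribution of the log-rank statistic (<= 8 obs)."""
    n = len(time)
    n1 = int(np.sum(group))
    obs, _ = statistic_fn(time, event, group)
    count = total = 0
    for ones in itertools.combinations(range(n), n1):
        g = np.zeros(n, dtype=int)
        g[list(ones)] = 1
        s, _ = statistic_fn(time, event, g)
        if not np.isfinite(s):
            s = 0.0
        total += 1
        if s >= obs - 1e-9:
            count += 1
    return count / total


class TestLogrank:
    def test_matches_lifelines_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 80))
            t = rng.exponential(20, n)
            e = rng.random(n) < 0.7
            g = (rng.random(n) < 0.5).astype(int)
            if e.sum() == 0 or g.sum() in (0, n):
                continue
            chi2, p = logrank_two_group(t, e, g)
            ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
            assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_no_events_undefined(self):
        chi2, p = logrank_two_group([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert np.isnan(chi2) and np.isnan(p)

    def test_permutation_oracle_small_sample(self):
        # 8 observations: compare the chi-square p to the exact permutation p
        t = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1], dtype=bool)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        _, p_chi = logrank_two_group(t, e, g)
        p_perm = permutation_logrank_p(t, e, g, logrank_two_group)
        assert abs(p_chi - p_perm) < 0.12

    def test_km_logrank_shapes_and_flags(self, rng):
        df = pd.DataFrame({"t": rng.exponential(30, 60),
                           "e": rng.random(60) < 0.6,
                           "g": rng.choice(["A", "B"], 60)})
        out = km_logrank(df, "t", "e", "g")
        assert out["test_defined"] and set(out["curves"]) == {"A", "B"}
        single = km_logrank(df.assign(g="A"), "t", "e", "g")
        assert not single["test_defined"] and single["logrank_p"] is None

    def test_km_all_censored(self):
        df = pd.DataFrame({"t": [5.0, 6.0, 7.0, 8.0], "e": [0, 0, 0, 0],
                           "g": ["A", "A", "B", "B"]})
        out = km_logrank(df, "t", "e", "g")
        assert not out["test_defined"]
        for curve in out["curves"].values():
            assert (curve.to_numpy() == 1.0).all()


class TestCox:
    def _surv(self, rng, n=400, beta=1.0):
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.02 * np.exp(beta * x)))
        c = rng.exponential(60, n)
        return pd.DataFrame({"x": x, "t": np.minimum(t, c), "e": t <= c})

    def test_recovers_hazard_ratio(self, rng):
        df = self._surv(rng, beta=np.log(2.0))
        res = cox_fit(df, ["x"], "t", "e")
        assert res.hazard_ratios["x"] == pytest.approx(2.0, rel=0.2)
        lo, hi = res.confidence_intervals["x"]
        assert lo < res.hazard_ratios["x"] < hi
        assert res.model_type == "univariate"

    def test_duplicated_covariate_raises(self, rng):
        df = self._surv(rng)
        df["x2"] = df["x"]
        with pytest.raises(CoxConvergenceError):
            cox_fit(df, ["x", "x2"], "t", "e")

    def test_constant_covariate_raises(self, rng):
        df = self._surv(rng).assign(z=1.0)
        with pytest.raises(CoxConvergenceError):
            cox_fit(df, ["z"], "t", "e")

    def test_sparse_events_warn(self, rng):
        df = self._surv(rng, n=60)
        df.loc[df.index[8:], "e"] = False
        with pytest.warns(UserWarning, match="events"):
            cox_fit(df, ["x"], "t", "e")


class TestPropensityMatch:
    def _cohorts(self, rng, n_cases=25, n_controls=400, shift=0.0):
        cases = pd.DataFrame({
            "sample_id": [f"c{i}" for i in range(n_cases)],
            "thickness_mm": rng.normal(6 + shift, 1.5, n_cases),
            "diameter_mm": rng.normal(13 + shift, 2.5, n_cases)})
        controls = pd.DataFrame({
            "sample_id": [f"k{i}" for i in range(n_controls)],
            "thickness_mm": rng.normal(6, 1.5, n_controls),
            "diameter_mm": rng.normal(13, 2.5, n_controls)})
        return cases, controls

    def test_full_three_to_one_match(self, rng):
        cases, controls = self._cohorts(rng)
        res = propensity_match(cases, controls)
        assert len(res.matched_controls) == 75
        assert not res.partial
        assert all(len(v) == 3 for v in res.control_ids_per_case.values())
        # without replacement
        flat = [j for v in res.control_ids_per_case.values() for j in v]
        assert len(flat) == len(set(flat))

    def test_matching_improves_balance(self, rng):
        cases, controls = self._cohorts(rng, shift=1.5)
        res = propensity_match(cases, controls)
        for v in ("thickness_mm", "diameter_mm"):
            assert res.smd_after[v] <= res.smd_before[v] + 1e-9

    def test_exact_duplicates_give_zero_smd(self):
        cases = pd.DataFrame({"sample_id": ["c0", "c1"],
                              "thickness_mm": [5.0, 6.0],
                              "diameter_mm": [12.0, 13.0]})
        controls = pd.DataFrame({
            "sample_id": [f"k{i}" for i in range(9)],
            "thickness_mm": [5.0] * 3 + [6.0] * 3 + [9.0, 9.5, 10.0],
            "diameter_mm": [12.0] * 3 + [13.0] * 3 + [20.0, 21.0, 22.0]})
        res = propensity_match(cases, controls)
        assert sorted(res.control_ids_per_case["c0"]) == ["k0", "k1", "k2"]
        assert sorted(res.control_ids_per_case["c1"]) == ["k3", "k4", "k5"]
        assert res.smd_after["thickness_mm"] == pytest.approx(0.0, abs=1e-9)
        assert res.smd_after["diameter_mm"] == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_controls_rejected(self, rng):
        cases, controls = self._cohorts(rng, n_cases=25, n_controls=50)
        with pytest.raises(ValueError):
            propensity_match(cases, controls)


class TestSurvivalAtTimes:
    def test_surface_monotone_and_near_km(self, rng):
        x = rng.normal(size=500)
        t = rng.exponential(1.0 / (0.03 * np.exp(0.7 * x)))
        df = pd.DataFrame({"x": x, "t": np.minimum(t, 80.0), "e": t <= 80.0})
        out = survival_at_times(df, "x", "t", "e", times=[12, 24, 36, 48, 60])
        surf = out["surface"]
        # decreasing in time for every covariate value
        assert (surf.diff().dropna() <= 1e-12).all().all()
        # higher covariate -> worse survival at every time
        assert (surf.diff(axis=1).dropna(axis=1) <= 1e-12).all().all()
        assert out["extrapolated"] == []
        # S(t | median x) should sit near the overall KM curve
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter().fit(df["t"], df["e"])
        med = float(np.quantile(df["x"], 0.5))
        med_col = min(surf.columns, key=lambda c: abs(c - med))
        for tt in (12, 24, 36):
            km_s = float(kmf.survival_function_at_times(tt).iloc[0])
            assert abs(surf.loc[tt, med_col] - km_s) < 0.05

    def test_extrapolation_flagged(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=80),
                           "t": rng.uniform(1, 30, 80),
                           "e": rng.random(80) < 0.6})
        out = survival_at_times(df, "x", "t", "e", times=[12, 24, 48])
        assert out["extrapolated"] == [48]


class TestPower:
    def test_schoenfeld_frozen_design_value(self):
        out = schoenfeld_power(25, 85, 0.90, 0.70, 60.0)
        assert out["power"] == pytest.approx(0.7716, abs=2e-3)
        assert out["hazard_ratio"] == pytest.approx(3.385, abs=5e-3)
        assert out["expected_events"] == pytest.approx(28.0, abs=0.1)

    def test_invalid_survival_rejected(self):
        with pytest.raises(ValueError):
            schoenfeld_power(10, 10, 1.0, 0.5, 60.0)

    def test_null_design_calibrated_near_alpha(self):
        res = logrank_power((40, 40), (0.7, 0.7), n_reps=2000, seed=3)
        assert abs(res.estimated_power - 0.05) < 3 * max(res.mc_se, 0.005) + 0.01

    def test_power_monotone_in_sample_size(self):
        small = logrank_power((20, 20), (0.85, 0.60), n_reps=1500, seed=8)
        large = logrank_power((80, 80), (0.85, 0.60), n_reps=1500, seed=8)
        assert large.estimated_power > small.estimated_power

    def test_reproducible_and_reports_cross_check(self):
        a = logrank_power((25, 85), (0.90, 0.70), n_reps=500, seed=4)
        b = logrank_power((25, 85), (0.90, 0.70), n_reps=500, seed=4)
        assert a.estimated_power == b.estimated_power
        assert a.schoenfeld_power == pytest.approx(0.7716, abs=2e-3)
        assert 0.0 <= a.estimated_power <= 1.0
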