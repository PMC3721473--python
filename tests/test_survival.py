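import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ovca.simulate import simulate_dose_response, simulate_survival
from ovca.survival import (
    cox_fit,
    fisher_exact,
    gi50,
    km_estimate,
    logrank_test,
    mann_whitney_u,
    spearman_matrix,
)


def brute_fisher_p(table):
    """Full enumeration over all tables with the observed margins."""
    a, b, c, d = np.asarray(table).ravel()
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, n, r1, c1)
        if px <= obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


class TestKm:
    def test_hand_product_limit(self):
        curves = km_estimate([1.0, 2.0], [1, 1])
        c = curves["all"].set_index("time")["survival"]
        assert c[1.0] == 0.5
        assert c[2.0] == 0.0

    def test_all_censored_flat(self):
        curves = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curves["all"]["survival"] == 1.0).all()

    def test_duplication_invariance(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        single = km_estimate(t, e)["all"]
        double = km_estimate(t * 2, e * 2)["all"]
        pd.testing.assert_series_equal(single["survival"], double["survival"])

    def test_non_increasing_and_starts_at_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50) + 0.01
        e = rng.integers(0, 2, 50)
        e[0] = 1
        curve = km_estimate(t, e)["all"]
        assert curve["survival"].iloc[0] == 1.0
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(10, 80) + 0.01
        e = rng.integers(0, 2, 80)
        e[:5] = 1
        curve = km_estimate(t, e)["all"]
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in curve.iterrows():
            assert kmf.predict(row["time"]) == pytest.approx(row["survival"], abs=1e-10)


class TestLogrank:
    def test_hand_two_sample(self):
        chi2, df, p = logrank_test([1.0, 2.0], [1, 1], ["A", "B"])
        assert chi2 == pytest.approx(1.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0] * 2
        e = [1, 1, 0] * 2
        g = ["A"] * 3 + ["B"] * 3
        chi2, _, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_df1_identity(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 60) + 0.01
        e = rng.integers(0, 2, 60)
        e[:3] = 1
        g = rng.choice(["A", "B"], 60)
        chi2, df, _ = logrank_test(t, e, g)
        from lifelines.statistics import logrank_test as ll_logrank

        res = ll_logrank(t[g == "A"], t[g == "B"], e[g == "A"], e[g == "B"])
        assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)

    def test_three_groups_df2(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 90) + 0.01
        e = np.ones(90, dtype=int)
        g = np.repeat(["A", "B", "C"], 30)
        _, df, _ = logrank_test(t, e, g)
        assert df == 2


class TestCox:
    def test_constant_covariate_error(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1.0, 2.0, 3.0], [1, 1, 1], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_single_event_conditional_logistic(self):
        # one event among 3 at-risk: score equation sum x_i e^{bx_i} = x_event * sum e^{bx_i}
        # with x = (1, 0, 0) and the event on x=1: beta solves e^b/(e^b+2) -> ML at +inf;
        # use event on x=0 instead: e^b/(e^b+2) = 0 has no finite root either, so take
        # a balanced toy: events on both levels
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 0]
        x = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0]})
        fit = cox_fit(t, e, x)
        # oracle: maximize the Breslow partial likelihood numerically
        from scipy.optimize import minimize_scalar

        def nll(b):
            # event at t=1 (x=1, risk {all}); event at t=2 (x=0, risk {2,3,4})
            ll = b - np.log(2 * np.exp(b) + 2) + 0 - np.log(np.exp(b) + 2)
            return -ll

        oracle = minimize_scalar(nll, bounds=(-5, 5), method="bounded").x
        assert fit.loc["x", "coef"] == pytest.approx(oracle, abs=1e-5)

    def test_recovers_true_hr(self):
        labels = ["A"] * 800 + ["B"] * 800
        table = simulate_survival(labels, hazard_ratios={"B": 2.0},
                                  censoring_rate=0.2, rng_seed=9)
        x = (table.table["subtype"] == "B").astype(float).to_frame("b")
        fit = cox_fit(table.table["os_time"], table.table["os_event"], x)
        assert 1.6 < fit.loc["b", "hr"] < 2.5

    def test_duplication_invariance(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 100) + 0.01
        e = rng.integers(0, 2, 100)
        e[:10] = 1
        x = pd.DataFrame({"x": rng.normal(size=100)})
        single = cox_fit(t, e, x)
        double = cox_fit(np.tile(t, 2), np.tile(e, 2), pd.concat([x, x], ignore_index=True))
        assert double.loc["x", "coef"] == pytest.approx(single.loc["x", "coef"], abs=1e-6)
        assert double.loc["x", "se"] == pytest.approx(single.loc["x", "se"] / np.sqrt(2), rel=1e-3)

    def test_matches_lifelines_breslow(self):
        rng = np.random.default_rng(6)
        n = 150
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, n).astype(float)
        t = rng.exponential(1 / np.exp(0.5 * x1 - 0.3 * x2)) + 1e-6
        e = rng.integers(0, 2, n)
        e[:10] = 1
        fit = cox_fit(t, e, pd.DataFrame({"x1": x1, "x2": x2}))
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"T": t, "E": e, "x1": x1, "x2": x2})
        # continuous times: no ties, so Efron == Breslow
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit["coef"], cph.params_[["x1", "x2"]], atol=1e-5)
        np.testing.assert_allclose(fit["se"], cph.standard_errors_[["x1", "x2"]], atol=1e-5)


class TestFisher:
    def test_hand_enumeration_third(self):
        p, _ = fisher_exact([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_odds_ratio_cross_product(self):
        _, odds = fisher_exact([[10, 2], [3, 15]])
        assert odds == pytest.approx(25.0)

    def test_equal_rows_p_one(self):
        p, _ = fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_negative_cell(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    def test_matches_enumeration_oracle_small_tables(self):
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            if a + b + c + d > 12:
                continue
            p, _ = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(brute_fisher_p([[a, b], [c, d]]), abs=1e-10)


class TestMannWhitney:
    def test_extreme_ordering(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_interleaved_p_one(self):
        u, p = mann_whitney_u([1, 4], [2, 3])
        assert u == 2.0
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_type_one_rate(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            mann_whitney_u(rng.normal(size=15), rng.normal(size=15))[1] < 0.05
            for _ in range(200)
        )
        assert 2 <= rejections <= 22


class TestSpearman:
    def test_monotone_transform_rho_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, _ = spearman_matrix(pd.DataFrame({"x": x, "y": np.exp(x)}))
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_reversal_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rho, _ = spearman_matrix(pd.DataFrame({"x": x, "y": x[::-1]}))
        assert rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_midrank_hand_value(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 3.0, 2.0, 4.0]
        rho, _ = spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        # midranks x = [1, 2.5, 2.5, 4], y = [1, 3, 2, 4]; Pearson of ranks
        rx = np.array([1, 2.5, 2.5, 4.0])
        ry = np.array([1, 3.0, 2.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9486832980505138, abs=1e-9)

    def test_constant_column_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]}))
        assert np.isnan(rho.loc["x", "y"])


class TestGi50:
    def test_analytic_hill_midpoint(self):
        conc = 1000 / 2.0 ** np.arange(9)[::-1]
        viab = 100 / (1 + conc / 10.0)
        value, status = gi50(conc, viab)
        assert status == "ok"
        assert abs(value - 10.0) / 10.0 < 0.01

    def test_censored_above_max(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0])
        viab = np.array([95.0, 90.0, 85.0, 80.0])
        value, status = gi50(conc, viab)
        assert status == "> max dose"
        assert np.isnan(value)

    def test_interp_mode(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0])
        viab = np.array([80.0, 60.0, 40.0, 20.0])
        value, status = gi50(conc, viab, model="loglinear-interp")
        assert status == "ok"
        assert 2.0 < value < 4.0

    def test_noisy_recovery(self):
        conc = 1000 / 2.0 ** np.arange(9)[::-1]
        estimates = []
        for seed in range(60):
            table = simulate_dose_response(25.0, 1.2, conc, noise_sd=3.0, rng_seed=seed)
            value, status = gi50(table["concentration"], table["viability"])
            if status == "ok":
                estimates.append(value)
        assert abs(np.median(estimates) - 25.0) / 25.0 < 0.10

    def test_monotone_contract(self):
        conc = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        low = np.array([90.0, 70.0, 45.0, 25.0, 10.0])
        high = low + 8.0
        g_low, _ = gi50(conc, low, model="loglinear-interp")
        g_high, _ = gi50(conc, high, model="loglinear-interp")
        assert g_high >= g_low
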