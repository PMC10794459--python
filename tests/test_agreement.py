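"""ICC(2,1), log-scale Bland-Altman, ratio metrics and sample-size planning."""

import numpy as np
import pandas as pd
import pytest

import tiltlab as tl

from conftest import make_threshold_table


def icc_mean_squares_oracle(X):
    """Direct-summation mean squares for the two-way subject x session layout."""
    n, k = X.shape
    g = X.mean()
    msr = k * sum((X[i].mean() - g) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((X[:, j].mean() - g) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (X[i, j] - X[i].mean() - X[:, j].mean() + g) ** 2
        for i in range(n)
        for j in range(k)
    )
    return msr, msc, sse / ((n - 1) * (k - 1))


class TestICC:
    def test_identical_columns_give_one(self, rng):
        col = rng.normal(size=12) * 4
        res = tl.icc_2_1(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        res = tl.icc_2_1(rng.normal(size=(500, 2)))
        assert abs(res.icc) < 0.1

    def test_hand_matrix_matches_mean_squares_oracle(self):
        X = np.array([[9.0, 10.0], [6.0, 7.5], [8.0, 8.5], [7.0, 6.0], [10.0, 11.5], [6.5, 7.0]])
        res = tl.icc_2_1(X)
        msr, msc, mse = icc_mean_squares_oracle(X)
        assert res.msr == pytest.approx(msr, rel=1e-10)
        assert res.msc == pytest.approx(msc, rel=1e-10)
        assert res.mse == pytest.approx(mse, rel=1e-10)
        expected = (msr - mse) / (msr + (2 - 1) * mse + 2 * (msc - mse) / 6)
        assert res.icc == pytest.approx(expected, rel=1e-10)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1)) * 2
        res = tl.icc_2_1(X)
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(10), 3),
                "rater": np.tile(["a", "b", "c"], 10),
                "y": X.ravel(),
            }
        )
        ref = pg.intraclass_corr(data=long, targets="subj", raters="rater", ratings="y")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0] if (ref["Type"] == "ICC(A,1)").any() else ref[ref["Type"] == "ICC2"].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], rel=1e-9)
        lo, hi = row[ref.columns[-1]]
        assert res.ci_low == pytest.approx(lo, abs=0.005)
        assert res.ci_high == pytest.approx(hi, abs=0.005)

    def test_missing_cells_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        X[2, 1] = np.nan
        with pytest.raises(ValueError):
            tl.icc_2_1(X)

    @pytest.mark.parametrize("true_icc", [0.5, 0.75, 0.9])
    def test_ci_covers_truth_at_study_scale(self, true_icc):
        """At n=18 pairs the 95% CI contains the generating ICC in >= 90% of draws."""
        rng = np.random.default_rng(int(true_icc * 100))
        pop = tl.ObserverPopulationConfig.with_true_icc(true_icc)
        cover = 0
        for _ in range(500):
            X = tl.sample_log_threshold_matrix(pop, 18, 2, rng=rng)
            res = tl.icc_2_1(X)
            cover += res.ci_low <= true_icc <= res.ci_high
        assert cover / 500 >= 0.90


class TestBlandAltman:
    def test_identity_pairs(self, rng):
        web = np.exp(rng.normal(size=10))
        res = tl.bland_altman_log(web, web)
        assert res.mean_ratio == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(1.0)
        assert res.loa_high == pytest.approx(1.0)

    def test_doubled_lab_thresholds(self, rng):
        web = np.exp(rng.normal(size=15))
        with pytest.warns(UserWarning):  # constant log difference fails normality
            res = tl.bland_altman_log(web, 2.0 * web)
        assert res.mean_ratio == pytest.approx(2.0)  # ratio > 1 means lab larger

    def test_scale_invariance(self, rng):
        web = np.exp(rng.normal(size=20))
        lab = web * np.exp(rng.normal(0, 0.2, size=20))
        r1 = tl.bland_altman_log(web, lab)
        r2 = tl.bland_altman_log(web * 37.2, lab * 37.2)
        assert r1.mean_ratio == pytest.approx(r2.mean_ratio)
        assert r1.loa_low == pytest.approx(r2.loa_low)
        assert r1.loa_high == pytest.approx(r2.loa_high)

    def test_label_swap_inverts_ratios(self, rng):
        web = np.exp(rng.normal(size=20))
        lab = web * np.exp(rng.normal(0.1, 0.2, size=20))
        fwd = tl.bland_altman_log(web, lab)
        rev = tl.bland_altman_log(lab, web)
        assert rev.mean_ratio == pytest.approx(1.0 / fwd.mean_ratio)
        assert rev.loa_low == pytest.approx(1.0 / fwd.loa_high)
        assert rev.loa_high == pytest.approx(1.0 / fwd.loa_low)
        assert tl.median_absolute_ratio(web, lab)[0] == pytest.approx(
            tl.median_absolute_ratio(lab, web)[0]
        )

    def test_loa_cover_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.0, 0.25, size=10_000)
        with pytest.warns(UserWarning):  # Shapiro on huge n warns upstream
            res = tl.bland_altman_log(np.ones_like(d), np.exp(d))
        inside = (res.loa_low <= np.exp(d)) & (np.exp(d) <= res.loa_high)
        assert inside.mean() == pytest.approx(0.95, abs=0.01)

    def test_nonpositive_threshold_names_pair(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            tl.bland_altman_log([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


class TestMedianAbsoluteRatio:
    def test_identical_pairs(self):
        assert tl.median_absolute_ratio([1, 2, 3], [1, 2, 3]) == (1.0, 0.0)

    def test_symmetric_ratios(self):
        web = np.array([1.0, 1.0, 1.0, 1.0])
        lab = np.array([2.0, 0.5, 2.0, 0.5])
        med, iqr = tl.median_absolute_ratio(web, lab)
        assert med == pytest.approx(2.0)
        assert iqr == pytest.approx(0.0)

    def test_lognormal_noise_matches_monte_carlo_oracle(self):
        """Median absolute ratio under independent session noise sigma=0.2.

        d ~ N(0, 0.2*sqrt(2)); median |d| = 0.2*sqrt(2)*Phi^-1(0.75)."""
        from scipy.stats import norm

        rng = np.random.default_rng(4)
        web = np.exp(rng.normal(0, 0.2, 10_000))
        lab = np.exp(rng.normal(0, 0.2, 10_000))
        med, _ = tl.median_absolute_ratio(web, lab)
        expected = np.exp(0.2 * np.sqrt(2) * norm.ppf(0.75))
        assert med == pytest.approx(expected, rel=0.02)


class TestLearningCheck:
    def _table(self, Y_web, Y_lab, web_first=True):
        orders = {
            "web": [1 if web_first else 2] * Y_web.shape[0],
            "lab": [2 if web_first else 1] * Y_lab.shape[0],
        }
        return make_threshold_table({"web": Y_web, "lab": Y_lab}, session_orders=orders)

    def test_identical_sessions_give_exactly_one(self, rng):
        Y = np.exp(rng.normal(size=(6, 2, 4)))
        out = tl.learning_check(self._table(Y, Y))
        assert out["ratio_first_over_second"] == pytest.approx(1.0)

    def test_twenty_percent_improvement_detected(self, rng):
        Y = np.exp(rng.normal(size=(6, 2, 4)))
        out = tl.learning_check(self._table(Y, 0.8 * Y))  # second session 20% better
        assert out["ratio_first_over_second"] == pytest.approx(1.25)

    def test_no_learning_null_simulation(self):
        rng = np.random.default_rng(5)
        pop = tl.ObserverPopulationConfig(n_participants=18)
        obs = tl.draw_population(pop, rng=rng)
        rows = []
        for o in obs:
            for s in ("web", "lab"):
                for a, task in enumerate(("temporal", "spatial")):
                    for orient in (0.0, 90.0, -45.0, 45.0):
                        rows.append(
                            {
                                "participant_id": o.participant_id,
                                "session": s,
                                "session_order": o.session_order[s],
                                "task": task,
                                "orientation": orient,
                                "threshold": o.params(s, task, orient)[0],
                                "se_threshold": 0.1,
                            }
                        )
        out = tl.learning_check(pd.DataFrame(rows))
        assert out["ratio_first_over_second"] == pytest.approx(1.0, abs=0.05)

    def test_missing_order_rejected(self, rng):
        Y = np.exp(rng.normal(size=(4, 2, 4)))
        table = self._table(Y, Y)
        table["session_order"] = 1  # both sessions marked first: no pairing possible
        with pytest.raises(ValueError):
            tl.learning_check(table)


class TestSampleSize:
    def test_reproduces_published_planning_value(self):
        assert tl.sample_size_icc(0.50, 0.75, k_ratings=8, alpha=0.05, power=0.80) == 15

    def test_more_ratings_never_need_more_subjects(self):
        ns = [tl.sample_size_icc(0.5, 0.75, k) for k in range(2, 12)]
        assert all(b <= a for a, b in zip(ns, ns[1:]))

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            tl.sample_size_icc(0.8, 0.5, 4)
        with pytest.raises(ValueError):
            tl.sample_size_icc(0.5, 0.5, 4)

    def test_planned_n_achieves_nominal_power(self):
        """Monte-Carlo power oracle: one-sided 0.05-level rejection of ICC0=0.2
        at the planned n when the true ICC is 0.8 should be near 80%."""
        n = tl.sample_size_icc(0.2, 0.8, k_ratings=3, alpha=0.05, power=0.80)
        rng = np.random.default_rng(6)
        pop = tl.ObserverPopulationConfig.with_true_icc(0.8)
        rej = 0
        n_rep = 600
        for _ in range(n_rep):
            X = tl.sample_log_threshold_matrix(pop, n, 3, rng=rng)
            res = tl.icc_2_1(X, alpha=0.10)  # 90% two-sided -> one-sided 5% bound
            rej += res.ci_low > 0.2
        assert rej / n_rep == pytest.approx(0.80, abs=0.08)


class TestAgreementAnalysis:
    def test_full_bundle_on_simulated_tables(self, rng):
        pop = tl.ObserverPopulationConfig.with_true_icc(0.9, n_participants=18)
        obs = tl.draw_population(pop, rng=rng)
        rows = []
        for o in obs:
            for s in ("web", "lab"):
                for task in ("temporal", "spatial"):
                    for orient in (0.0, 90.0, -45.0, 45.0):
                        rows.append(
                            {
                                "participant_id": o.participant_id,
                                "session": s,
                                "session_order": o.session_order[s],
                                "task": task,
                                "orientation": orient,
                                "threshold": o.params(s, task, orient)[0],
                                "se_threshold": 0.1,
                            }
                        )
        table = pd.DataFrame(rows)
        results = tl.agreement_analysis(table)
        assert set(results) == {"temporal", "spatial"}
        for res in results.values():
            assert res.n_pairs == 18 * 4
            assert res.bland_altman.loa_low <= res.bland_altman.mean_ratio <= res.bland_altman.loa_high
            assert res.median_abs_ratio >= 1.0
            assert -1 < res.icc.icc <= 1

    def test_missing_session_rejected(self, rng):
        Y = np.exp(rng.normal(size=(5, 2, 4)))
        table = make_threshold_table({"web": Y})
        with pytest.raises(ValueError, match="lab"):
            tl.agreement_analysis(table)
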