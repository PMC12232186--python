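"""Concordance statistics and the survival-analysis layer."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import friedmanchisquare

from tilquant.stats import (
    classify_reliability,
    coefficient_of_variation,
    cox_fit,
    icc,
    icc_forms_table,
    kendall_w,
    km_logrank,
    log_transform,
    median_followup,
    schoenfeld_test,
)
from tilquant.synthetic import (
    SimulationConfig,
    simulate_clark_matrix,
    simulate_score_matrix,
    simulate_survival_cohort,
)


def _brute_force_icc2(x: np.ndarray) -> float:
    """Explicit two-way ANOVA mean squares -> ICC(2,1)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestLogTransform:
    def test_zero_with_offset_one_maps_to_zero(self):
        m = pd.DataFrame([[0.0, 5.0]])
        out = log_transform(m)
        assert out.iloc[0, 0] == 0.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame([[-1.0]]))

    def test_matches_log1p_and_preserves_order_and_missing(self, rng):
        m = pd.DataFrame(rng.uniform(0, 100, (6, 4)))
        m.iloc[2, 1] = np.nan
        out = log_transform(m)
        assert np.allclose(
            out.to_numpy(), np.log1p(m.to_numpy()), equal_nan=True
        )
        col = m.iloc[:, 0].to_numpy()
        assert (np.argsort(out.iloc[:, 0].to_numpy()) == np.argsort(col)).all()
        assert np.isnan(out.iloc[2, 1])


class TestICC:
    def test_identical_raters_give_one(self):
        m = pd.DataFrame({"r1": [1.0, 5.0, 9.0], "r2": [1.0, 5.0, 9.0]})
        assert icc(m).value == pytest.approx(1.0)

    def test_hand_matrix_equals_anova_formula(self):
        m = pd.DataFrame(
            [[9.0, 2.0, 5.0], [6.0, 1.0, 3.0], [8.0, 4.0, 6.0], [7.0, 1.0, 2.0]]
        )
        assert icc(m, form="ICC2").value == pytest.approx(
            _brute_force_icc2(m.to_numpy()), abs=1e-10
        )

    def test_random_matrices_equal_anova_formula(self, rng):
        for _ in range(20):
            x = rng.normal(10, 3, (rng.integers(4, 9), rng.integers(3, 7)))
            assert icc(pd.DataFrame(x), form="ICC2").value == pytest.approx(
                _brute_force_icc2(x), abs=1e-10
            )

    def test_all_forms_match_pingouin(self, rng):
        import pingouin as pg

        x = pd.DataFrame(rng.normal(10, 3, (8, 4)))
        long = x.reset_index().melt(id_vars="index", var_name="rater", value_name="v")
        ref = pg.intraclass_corr(
            long, targets="index", raters="rater", ratings="v"
        ).set_index("Type")
        mine = icc_forms_table(x)
        mapping = {
            "ICC(1,1)": "ICC1",
            "ICC(A,1)": "ICC2",
            "ICC(C,1)": "ICC3",
            "ICC(1,k)": "ICC1k",
            "ICC(A,k)": "ICC2k",
            "ICC(C,k)": "ICC3k",
        }
        for pg_name, name in mapping.items():
            assert mine.loc[name, "value"] == pytest.approx(
                ref.loc[pg_name, "ICC"], abs=1e-10
            )
            lo, hi = ref.loc[pg_name, "CI95"]
            assert mine.loc[name, "ci_lower"] == pytest.approx(lo, abs=0.01)
            assert mine.loc[name, "ci_upper"] == pytest.approx(hi, abs=0.01)

    def test_invariant_to_reordering(self, rng):
        x = pd.DataFrame(rng.normal(0, 1, (7, 5)))
        base = icc(x).value
        rows = rng.permutation(7)
        cols = rng.permutation(5)
        assert icc(x.iloc[rows, cols]).value == pytest.approx(base, abs=1e-12)

    def test_casewise_deletion_counts_dropped(self):
        m = pd.DataFrame(np.arange(12.0).reshape(4, 3) + np.eye(4, 3))
        m.iloc[1, 2] = np.nan
        res = icc(m)
        assert res.n_dropped_cases == 1
        assert res.n_cases == 3

    def test_too_few_raters_rejected(self):
        with pytest.raises(ValueError):
            icc(pd.DataFrame({"r1": [1.0, 2.0, 3.0]}))

    def test_ci_brackets_value(self):
        m = simulate_score_matrix(SimulationConfig(seed=0))
        res = icc(m)
        assert res.ci[0] <= res.value <= res.ci[1]


class TestKendallW:
    def test_unanimous_raters_give_one(self):
        m = pd.DataFrame({"r1": [1, 2, 3, 3], "r2": [1, 2, 3, 3], "r3": [1, 2, 3, 3]})
        assert kendall_w(m).value == pytest.approx(1.0)

    def test_reversed_rankings_give_zero(self):
        m = pd.DataFrame({"r1": [1, 2, 3, 4], "r2": [4, 3, 2, 1]})
        assert kendall_w(m).value == pytest.approx(0.0)

    def test_matches_friedman_statistic_with_ties(self, rng):
        """chi2 = m (n-1) W equals scipy's tie-corrected Friedman test
        (cases as treatments, raters as blocks)."""
        for seed in range(5):
            m = simulate_clark_matrix(
                SimulationConfig(seed=seed, n_cases=8, n_raters=5)
            )
            res = kendall_w(m)
            fried = friedmanchisquare(*[m.iloc[i, :] for i in range(len(m))])
            assert res.extra["chi2"] == pytest.approx(fried.statistic, abs=1e-10)

    def test_all_constant_raters_rejected(self):
        m = pd.DataFrame({"r1": [2, 2, 2], "r2": [1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            kendall_w(m)

    def test_invariant_to_reordering(self, rng):
        m = simulate_clark_matrix(SimulationConfig(seed=4, n_cases=10, n_raters=6))
        base = kendall_w(m).value
        perm = m.iloc[rng.permutation(10), rng.permutation(6)]
        assert kendall_w(perm).value == pytest.approx(base, abs=1e-12)


class TestReliabilityBands:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.94, "excellent"),
            (0.81, "excellent"),
            (0.80, "good"),
            (0.61, "good"),
            (0.60, "moderate"),
            (0.44, "moderate"),
            (0.40, "moderate"),
            (0.39, "poor"),
        ],
    )
    def test_band_edges(self, value, band):
        assert classify_reliability(value) == band

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_reliability(1.1)


class TestCV:
    def test_identical_values_give_zero(self):
        per_case, med = coefficient_of_variation(pd.DataFrame([[3.0, 3.0, 3.0]]))
        assert per_case.iloc[0] == 0.0

    def test_hand_example(self):
        per_case, med = coefficient_of_variation(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert per_case.iloc[0] == pytest.approx(0.5)
        assert med == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        m = pd.DataFrame(rng.uniform(1, 10, (5, 4)))
        base, _ = coefficient_of_variation(m)
        scaled, _ = coefficient_of_variation(7.3 * m)
        assert np.allclose(base, scaled)

    def test_zero_mean_case_is_missing(self):
        per_case, _ = coefficient_of_variation(pd.DataFrame([[1.0, -1.0]]))
        assert np.isnan(per_case.iloc[0])


def _cohort(seed=0, **kw):
    return simulate_survival_cohort(SimulationConfig(seed=seed, **kw))


class TestKMLogrank:
    def test_identical_groups_give_null_result(self):
        df = pd.DataFrame(
            {
                "time_months": [5, 10, 15, 5, 10, 15],
                "event": [1, 1, 0, 1, 1, 0],
                "group": [0, 0, 0, 1, 1, 1],
            }
        )
        res = km_logrank(df)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_worked_six_subject_example(self):
        """Log-rank chi-square from explicit risk-table arithmetic."""
        df = pd.DataFrame(
            {
                "time_months": [6.0, 7.0, 10.0, 7.0, 9.0, 11.0],
                "event": [1, 0, 1, 1, 1, 0],
                "group": [0, 0, 0, 1, 1, 1],
            }
        )
        # brute-force O-E and variance over distinct event times
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(df.loc[df["event"] == 1, "time_months"].unique()):
            at_risk = df["time_months"] >= t
            d = int(((df["time_months"] == t) & (df["event"] == 1)).sum())
            n = int(at_risk.sum())
            n1 = int((at_risk & (df["group"] == 1)).sum())
            d1 = int(
                ((df["time_months"] == t) & (df["event"] == 1) & (df["group"] == 1)).sum()
            )
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        res = km_logrank(df)
        assert res.chi2 == pytest.approx(expected_chi2, abs=1e-9)

    def test_single_group_rejected(self):
        df = pd.DataFrame(
            {"time_months": [1.0, 2.0], "event": [1, 1], "group": [0, 0]}
        )
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(df)

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"time_months": [1.0, 2.0], "event": [0, 0], "group": [0, 1]}
        )
        with pytest.raises(ValueError, match="event"):
            km_logrank(df)


class TestCox:
    def test_protective_group_effect_recovered(self):
        df = _cohort(seed=3)
        fit = cox_fit(df, ("group",))
        assert fit.summary.loc["group", "hr"] < 1.0
        assert fit.summary.loc["group", "ci_lower"] < fit.summary.loc["group", "hr"]

    def test_sign_agrees_with_logrank_direction(self):
        df = _cohort(seed=8)
        fit = cox_fit(df, ("group",))
        km = km_logrank(df)
        # group 1 has fewer events than expected <=> negative coefficient
        high = df[df["group"] == 1]
        expected_sign = np.sign(
            high["event"].sum()
            - df["event"].sum() * len(high) / len(df)
        )
        assert np.sign(fit.summary.loc["group", "coef"]) == expected_sign

    def test_duplicating_records_leaves_hr_nearly_unchanged(self):
        df = _cohort(seed=5)
        a = cox_fit(df, ("group",)).summary.loc["group", "hr"]
        b = cox_fit(pd.concat([df, df], ignore_index=True), ("group",)).summary.loc[
            "group", "hr"
        ]
        assert b == pytest.approx(a, rel=0.03)

    def test_all_censored_rejected(self):
        df = pd.DataFrame(
            {"time_months": [0.1, 0.1], "event": [0, 0], "group": [0, 1]}
        )
        with pytest.raises(ValueError, match="event"):
            cox_fit(df, ("group",))

    def test_constant_covariate_rejected(self):
        df = _cohort(seed=1).assign(group=1)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ("group",))

    def test_multivariable_adjustment_set(self):
        cfg = SimulationConfig(
            seed=9,
            n_subjects=400,
            covariate_log_hrs={"male": np.log(1.5), "stage_iii": np.log(4.5)},
        )
        df = simulate_survival_cohort(cfg)
        fit = cox_fit(df, ("group", "male", "age", "stage"))
        assert list(fit.summary.index) == [
            "group",
            "male",
            "age",
            "stage_ii",
            "stage_iii",
            "stage_iv",
        ]
        assert fit.summary.loc["stage_iii", "hr"] > 1.0

    def test_null_effect_ci_coverage(self):
        """Wald CI for a null group effect covers HR = 1 at ~95%."""
        cfg = SimulationConfig(seed=0, true_hr=1.0)
        rng = np.random.default_rng(0)
        cover = []
        while len(cover) < 200:
            df = simulate_survival_cohort(cfg, rng)
            try:
                s = cox_fit(df, ("group",)).summary.loc["group"]
            except ValueError:
                continue
            cover.append(s["ci_lower"] <= 1.0 <= s["ci_upper"])
        assert 0.90 <= np.mean(cover) <= 0.985


class TestSchoenfeld:
    def test_residuals_sum_to_zero(self):
        fit = cox_fit(_cohort(seed=5), ("group",))
        res = schoenfeld_test(fit)
        assert float(res.residuals.sum().abs().max()) < 1e-8

    def test_too_few_events_rejected(self):
        df = pd.DataFrame(
            {
                "time_months": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 0, 0],
                "group": [0, 1, 0, 1],
            }
        )
        fit = cox_fit(df, ("group",))
        with pytest.raises(ValueError, match="events"):
            schoenfeld_test(fit)

    def test_global_p_in_unit_interval(self):
        fit = cox_fit(_cohort(seed=2), ("group",))
        res = schoenfeld_test(fit)
        assert 0.0 <= res.global_p <= 1.0
        assert res.global_chi2 >= 0.0

    def test_detects_sign_flipping_effect(self):
        """A hazard effect that reverses mid-study is rejected with high
        power (piecewise-exponential cohorts, n = 500)."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_reps = 60
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_reps):
                n, beta, t0, lam, cens = 500, 1.0, 15.0, 0.02, 60.0
                x = rng.integers(0, 2, n)
                lam1 = lam * np.exp(beta * (2 * x - 1))
                lam2 = lam * np.exp(-beta * (2 * x - 1))
                t1 = rng.exponential(1 / lam1)
                t = np.where(t1 < t0, t1, t0 + rng.exponential(1 / lam2))
                c = rng.uniform(0, cens, n)
                df = pd.DataFrame(
                    {
                        "time_months": np.minimum(t, c),
                        "event": (t <= c).astype(int),
                        "group": x,
                    }
                )
                fit = cox_fit(df, ("group",))
                res = schoenfeld_test(fit)
                rejections += res.per_covariate.loc["group", "p"] < 0.05
        assert rejections / n_reps >= 0.8


def test_median_followup_direct():
    df = pd.DataFrame({"time_months": [10.0, 20.0, 30.0, 40.0, 50.0]})
    res = median_followup(df)
    assert res["median"] == 30.0
    assert res["method"] == "direct"
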