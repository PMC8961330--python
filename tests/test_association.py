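"""Regression, correlation, residualization and FDR primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from famloading import (
    AdjustedLinearModel,
    ModelError,
    aggregate_repeated_measures,
    bh_fdr,
    chi_square_2x2,
    fit_adjusted,
    pearson,
    point_biserial,
    residualize,
    run_full_analysis,
    student_t,
)


class TestAggregateRepeatedMeasures:
    @pytest.mark.parametrize(
        "waves,expected",
        [([10.0, 20.0, np.nan], 15.0), ([7.0], 7.0), ([1.0, 2.0, 3.0], 2.0)],
    )
    def test_mean_over_available_waves(self, waves, expected):
        assert aggregate_repeated_measures(waves) == pytest.approx(expected)

    def test_all_missing_propagates(self):
        assert np.isnan(aggregate_repeated_measures([np.nan, np.nan]))


def _toy_data(n, rng, beta=0.0):
    df = pd.DataFrame(
        {
            "age": rng.uniform(20, 70, n),
            "gender": rng.integers(0, 2, n),
            "education_years": rng.normal(13, 3, n),
            "fls": rng.normal(0, 1, n),
        }
    )
    df["y"] = beta * df["fls"] + rng.normal(0, 1, n)
    return df


class TestAdjustedModel:
    def test_null_effect(self):
        rng = np.random.default_rng(0)
        df = _toy_data(10_000, rng)
        res = fit_adjusted(df, "y", "fls")
        assert abs(res.beta) < 0.03
        assert res.ci_low <= res.b <= res.ci_high
        assert res.n_used == 10_000

    def test_perfect_association(self):
        rng = np.random.default_rng(1)
        df = _toy_data(500, rng)
        df["y"] = df["fls"]
        res = fit_adjusted(df, "y", "fls")
        assert res.beta == pytest.approx(1.0, abs=1e-8)
        assert res.p_raw < 1e-100

    def test_simulation_recovers_standardized_effect(self):
        """beta0 = 0.5 at n = 5000 over replicates, within 2 MC SEs."""
        rng = np.random.default_rng(2)
        betas = []
        for _ in range(100):
            df = _toy_data(5000, rng)
            df["y"] = 0.5 * (df["fls"] - df["fls"].mean()) / df["fls"].std() + np.sqrt(
                1 - 0.25
            ) * rng.normal(0, 1, 5000)
            betas.append(fit_adjusted(df, "y", "fls").beta)
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - 0.5) < 2 * se

    def test_matches_closed_form_simple_regression(self):
        """With no covariates the fit is the textbook least-squares line."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, 200)
        y = 1.5 * x + rng.normal(0, 1, 200)
        df = pd.DataFrame({"x": x})
        res = AdjustedLinearModel(exposure="x", covariates=()).fit(df, y)
        b_hat = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.coef_ == pytest.approx(b_hat, rel=1e-10)
        assert res.beta_ == pytest.approx(
            b_hat * np.std(x, ddof=1) / np.std(y, ddof=1), rel=1e-10
        )

    def test_full_standardization_equals_zscored_refit(self):
        """beta from sd-rescaling equals the coefficient of a z-scored refit."""
        rng = np.random.default_rng(4)
        df = _toy_data(300, rng, beta=0.3)
        res = fit_adjusted(df, "y", "fls")
        z = (df - df.mean()) / df.std(ddof=1)
        res_z = AdjustedLinearModel(exposure="fls").fit(z, z["y"])
        assert res.beta == pytest.approx(res_z.coef_, abs=1e-10)

    def test_errors(self):
        rng = np.random.default_rng(5)
        df = _toy_data(30, rng)
        with pytest.raises(ModelError, match="constant"):
            fit_adjusted(df.assign(fls=1.0), "y", "fls")
        with pytest.raises(ModelError, match="complete cases"):
            fit_adjusted(df.head(5), "y", "fls")
        with pytest.raises(ModelError, match="rank deficient"):
            fit_adjusted(df.assign(age=df["fls"] * 2), "y", "fls")


class TestResidualize:
    def test_group_mean_centering_by_hand(self):
        res = residualize([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        np.testing.assert_allclose(res, [-0.5, 0.5, -0.5, 0.5], atol=1e-12)

    def test_constant_within_group_gives_zero_residuals(self):
        res = residualize([2.0, 2.0, 5.0, 5.0], [0, 0, 1, 1])
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_orthogonality_and_zero_mean(self):
        rng = np.random.default_rng(0)
        fls = rng.normal(0, 1, 1000)
        fh = (rng.random(1000) < 0.6).astype(int)
        res = residualize(fls, fh)
        assert abs(res.mean()) < 1e-10
        assert abs(np.corrcoef(res, fh)[0, 1]) < 1e-10

    def test_single_level_fh_rejected(self):
        with pytest.raises(ModelError):
            residualize([1.0, 2.0], [1, 1])


class TestCorrelations:
    def test_point_biserial_equals_pearson_with_01_coding(self):
        rng = np.random.default_rng(1)
        b = (rng.random(500) < 0.4).astype(int)
        x = rng.normal(0, 1, 500) + b
        assert point_biserial(b, x) == pytest.approx(pearson(b.astype(float), x), abs=1e-12)

    def test_known_value(self):
        assert point_biserial([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0]) == pytest.approx(
            2 / np.sqrt(5), abs=1e-12
        )

    def test_no_group_difference_gives_zero(self):
        assert point_biserial([0, 1, 0, 1], [3.0, 3.0, 5.0, 5.0]) == pytest.approx(0.0)

    def test_perfect(self):
        assert point_biserial([0, 0, 1, 1], [0.0, 0.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ModelError):
            point_biserial([1, 1, 1], [1.0, 2.0, 3.0])
        with pytest.raises(ModelError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ModelError):
            pearson([1.0, 2.0], [1.0, 2.0])

    def test_independent_nulls(self):
        rng = np.random.default_rng(2)
        assert abs(pearson(rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000))) < 0.03


class TestStudentT:
    def test_pooled_df_is_n_minus_2(self):
        rng = np.random.default_rng(3)
        t, df, p = student_t(rng.normal(0, 1, 600), rng.normal(0.4, 1, 825))
        assert df == 1423
        assert t < 0 and p < 1e-6  # sign follows group order

    def test_identical_groups_give_zero(self):
        t, df, p = student_t([1.0, 2.0], [1.0, 2.0])
        assert t == pytest.approx(0.0) and df == 2

    def test_zero_pooled_variance_flagged(self):
        with pytest.raises(ModelError, match="degenerate"):
            student_t([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ModelError):
            student_t([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_printed_gender_table(self):
        chi2, df, p = chi_square_2x2([[191, 57], [949, 476]])
        assert round(chi2, 2) == 10.56
        assert df == 1 and p < 0.0012

    def test_identical_proportions(self):
        chi2, _, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_balanced_shift(self):
        chi2, _, _ = chi_square_2x2([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(4 * 25 / 15, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ModelError):
            chi_square_2x2([[0, 0], [5, 5]])


def bh_bruteforce(p, q):
    """Independent step-up oracle by direct enumeration of the BH condition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


class TestBHFDR:
    def test_worked_threshold_example(self):
        reject, _ = bh_fdr([0.001, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_rejects_none(self):
        reject, adj = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any() and np.all(adj == 1.0)

    def test_single_p_reduces_to_threshold(self):
        assert bh_fdr([0.04], q=0.05)[0].all()
        assert not bh_fdr([0.06], q=0.05)[0].any()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_agrees_with_bruteforce_and_statsmodels(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.3, 3)
            q = rng.uniform(0.01, 0.2)
            reject, adj = bh_fdr(p, q)
            np.testing.assert_array_equal(reject, bh_bruteforce(p, q))
            sm_reject, sm_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
            np.testing.assert_array_equal(reject, sm_reject)
            np.testing.assert_allclose(adj, sm_adj, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=200)
    def test_rejections_monotone_in_q(self, p):
        r1, _ = bh_fdr(p, q=0.05)
        r2, _ = bh_fdr(p, q=0.10)
        assert np.all(r2 | ~r1)  # everything rejected at 5% stays rejected at 10%


class TestFullPipeline:
    def test_row_count_and_shape(self, small_cohort):
        results, summary = run_full_analysis(small_cohort.participants)
        n_out = len(small_cohort.outcome_names)
        assert len(results) == 3 * n_out
        assert set(results["exposure"]) == {"fls", "fh", "fls_resid"}
        assert summary["r_fh_fls"] > 0.4
        assert summary["t_fls_by_fh"]["df"] == len(small_cohort.participants) - 2
        assert 0 < summary["fls_distribution"]["overlap_coefficient"] < 1

    def test_residualized_beta_invariant_to_fls_shift(self, small_cohort):
        p = small_cohort.participants
        r1, _ = run_full_analysis(p)
        p2 = p.assign(fls=p["fls"] + 100.0)
        r2, _ = run_full_analysis(p2)
        m1 = r1[r1.exposure == "fls_resid"].set_index("outcome")["beta"]
        m2 = r2[r2.exposure == "fls_resid"].set_index("outcome")["beta"]
        np.testing.assert_allclose(m1, m2, atol=1e-8)

    def test_global_family_option(self, small_cohort):
        results, _ = run_full_analysis(small_cohort.participants, bh_family="global")
        assert results["p_bh"].notna().all()
        with pytest.raises(ValueError):
            run_full_analysis(small_cohort.participants, bh_family="bonferroni")

    def test_missing_columns_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="fls"):
            run_full_analysis(small_cohort.participants.drop(columns=["fls"]))
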