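import numpy as np
import pandas as pd
import pytest

from pvcsurv.synthetic import CohortSpec, generate_cohort
from pvcsurv.synthetic.cohort import DEFAULT_EXERCISE_LOG_HR
from pvcsurv.survival import (
    AnalysisConfig,
    CoxResult,
    cumulative_incidence,
    fit_cox,
    floated_ci,
    floated_variances,
    impute,
    pool_rubin,
    run_analysis,
    schoenfeld_test,
)


def contrast_var_oracle(cov, i, j):
    """Var(beta_i - beta_j) with beta_0 = 0, by direct expansion."""
    full = np.zeros((cov.shape[0] + 1, cov.shape[0] + 1))
    full[1:, 1:] = cov
    return full[i, i] + full[j, j] - 2 * full[i, j]


class TestFitCox:
    def test_null_exposure_recovered_within_3se(self):
        spec = CohortSpec(
            n=12_000,
            exposure_log_hr={},
            recovery_log_hr={},
            confounding=0.0,
            missingness={},
            baseline_rate_female=0.009,
            baseline_rate_male=0.013,
        )
        df = generate_cohort(spec, seed=21)
        res = fit_cox(df, covariate_set="minimal")
        assert np.all(np.abs(res.beta.to_numpy()) < 3 * res.se.to_numpy())

    def test_planted_hrs_recovered(self, small_cohort):
        res = fit_cox(small_cohort, covariate_set="minimal")
        for cat, b in DEFAULT_EXERCISE_LOG_HR.items():
            name = f"exercise_category::{cat}"
            assert abs(res.beta[name] - b) < 3 * res.se[name]

    def test_omitted_confounder_shifts_estimates_upward(self):
        spec = CohortSpec(n=15_000, confounding=0.6, recovery_log_hr={}, missingness={},
                          baseline_rate_female=0.009, baseline_rate_male=0.013)
        df = generate_cohort(spec, seed=22)
        adjusted = fit_cox(df, covariates=("age", "n_beats_exercise"))
        crude = fit_cox(df, covariates=("n_beats_exercise",))
        # age raises both PVC burden and hazard; omitting it inflates the HRs
        assert np.all(crude.beta.to_numpy() > adjusted.beta.to_numpy())

    def test_unknown_endpoint_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            fit_cox(small_cohort, endpoint="stroke")

    def test_low_event_count_warns(self, small_cohort):
        with pytest.warns(UserWarning, match="events"):
            fit_cox(small_cohort.head(600), covariate_set="full")

    def test_schoenfeld_helper_flags_nonproportional_stratum(self):
        # make male baseline hazard 5x female: sex violates proportionality
        spec = CohortSpec(n=6000, missingness={}, recovery_log_hr={},
                          baseline_rate_female=0.004, baseline_rate_male=0.020)
        df = generate_cohort(spec, seed=23)
        res = fit_cox(df, covariate_set="minimal")
        out = schoenfeld_test(res)
        assert "sex" in out.index.get_level_values(0)


class TestFloated:
    def test_two_group_sum_identity_exact(self):
        cov = np.array([[0.04]])
        v = floated_variances(cov)
        assert v[0] + v[1] == pytest.approx(0.04, rel=1e-9)

    def test_diagonal_limit_floors_reference(self):
        cov = np.diag([0.02, 0.02, 0.02])
        v = floated_variances(cov)
        assert v[0] < 1e-6
        assert np.allclose(v[1:], 0.02, rtol=0.02)

    def test_reference_sharing_covariances_reconstruct_contrasts(self, rng):
        """Random shared-reference 4-group covariance fixtures: all pairwise
        contrast variances recovered within 10%."""
        for _ in range(25):
            u = rng.uniform(0.005, 0.05, size=5)
            cov = u[0] + np.diag(u[1:])
            v = floated_variances(cov)
            for i in range(5):
                for j in range(i + 1, 5):
                    truth = contrast_var_oracle(cov, i, j)
                    assert abs((v[i] + v[j]) / truth - 1.0) < 0.10

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError):
            floated_variances(np.array([[0.01, 0.05], [0.05, 0.01]]))

    def test_floated_ci_includes_reference_group(self, small_cohort):
        res = fit_cox(small_cohort, covariate_set="minimal")
        out = floated_ci(res)
        assert list(out.index) == res.categories
        ref = out.iloc[0]
        assert ref["hr"] == 1.0 and ref["lo"] < 1.0 < ref["hi"]
        # every group's floated CI brackets its point estimate
        assert np.all(out["lo"] < out["hr"]) and np.all(out["hr"] < out["hi"])


class TestImpute:
    def test_no_missing_returns_identical_copies(self, small_cohort):
        out = impute(small_cohort, m=3, iterations=2)
        assert len(out) == 3
        for c in out:
            pd.testing.assert_frame_equal(c, small_cohort)

    def test_pmm_preserves_observed_support_and_cells(self):
        df = generate_cohort(CohortSpec(n=2000, missingness={"ldl": 0.15, "smoking": 0.1}), seed=31)
        out = impute(df, m=2, iterations=3, seed=5)
        obs = df["ldl"].dropna()
        for c in out:
            assert c["ldl"].notna().all()
            # PMM only copies observed donor values
            assert np.isin(c.loc[df["ldl"].isna(), "ldl"], obs).all()
            filled_smoking = c.loc[df["smoking"].isna(), "smoking"]
            assert set(np.unique(filled_smoking)).issubset({0.0, 1.0})
            # observed cells untouched
            mask = df["ldl"].notna()
            assert np.array_equal(c.loc[mask, "ldl"], df.loc[mask, "ldl"])

    def test_mcar_mean_recovery(self):
        df = generate_cohort(CohortSpec(n=8000, missingness={"ldl": 0.10}), seed=32)
        complete_mean = generate_cohort(CohortSpec(n=8000, missingness={}), seed=32)["ldl"].mean()
        out = impute(df, m=3, iterations=4, seed=6)
        pooled = np.mean([c["ldl"].mean() for c in out])
        se = df["ldl"].std() / np.sqrt(len(df))
        assert abs(pooled - complete_mean) < 2 * se

    def test_illegal_missingness_rejected(self, small_cohort):
        df = small_cohort.copy()
        df.loc[df.index[:10], "age"] = np.nan
        with pytest.raises(ValueError, match="age"):
            impute(df)
        df2 = small_cohort.copy()
        df2["ldl"] = np.nan
        with pytest.raises(ValueError, match="fully missing"):
            impute(df2)


class TestPoolRubin:
    def _result(self, betas, var=0.01):
        names = pd.Index(["x::a", "x::b"])[: len(betas)]
        return CoxResult(
            exposure="x",
            categories=["ref"] + [n.split("::")[1] for n in names],
            reference="ref",
            beta=pd.Series(betas, index=names),
            se=pd.Series(np.sqrt(var), index=names),
            cov=pd.DataFrame(np.eye(len(betas)) * var, index=names, columns=names),
            p=pd.Series(0.5, index=names),
            covariate_set="minimal",
            endpoint="composite",
            strata="sex",
            n=1000,
            n_events=100,
        )

    def test_hand_built_rubin_arithmetic(self):
        results = [self._result([b]) for b in (0.1, 0.2, 0.3)]
        pooled = pool_rubin(results)
        assert pooled.beta.iloc[0] == pytest.approx(0.2)
        # between-variance of (0.1, 0.2, 0.3) is 0.01 -> total 0.01 + (4/3)*0.01
        assert pooled.se.iloc[0] ** 2 == pytest.approx(0.01 + (4 / 3) * 0.01, rel=1e-12)

    def test_identical_results_have_no_between_variance(self):
        results = [self._result([0.15, 0.3]) for _ in range(4)]
        pooled = pool_rubin(results)
        assert np.allclose(pooled.beta, [0.15, 0.3])
        assert np.allclose(pooled.se**2, 0.01)
        assert pooled.df_inference == pooled.n_events - 2

    def test_pooled_se_never_below_mean_within_se(self):
        rng = np.random.default_rng(8)
        results = [self._result(rng.normal(0.2, 0.05, size=2)) for _ in range(5)]
        pooled = pool_rubin(results)
        assert np.all(pooled.se.to_numpy() >= np.sqrt(0.01) - 1e-12)

    def test_mismatched_specs_rejected(self):
        a = self._result([0.1])
        b = self._result([0.1])
        b.endpoint = "MI"
        with pytest.raises(ValueError):
            pool_rubin([a, b])


class TestIncidence:
    def test_curves_start_at_zero_and_logrank_detects_effect(self, small_cohort):
        curves, p = cumulative_incidence(small_cohort, "exercise_category")
        for df_curve in curves.values():
            assert df_curve["cum_incidence"].iloc[0] == pytest.approx(0.0)
            assert df_curve["cum_incidence"].is_monotonic_increasing
        assert p < 0.05  # planted burden effect is detectable at n=6000

    def test_single_group_rejected(self, small_cohort):
        df = small_cohort.copy()
        df["one"] = "all"
        with pytest.raises(ValueError):
            cumulative_incidence(df, "one")


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(
        CohortSpec(n=4000, baseline_rate_female=0.0135, baseline_rate_male=0.0195),
        seed=41,
    )


class TestRunAnalysis:

    def test_composite_endpoint_counts_mi_hf_ltva(self, cohort):
        out = run_analysis(cohort, AnalysisConfig(covariate_set="minimal", m_imputations=2, mice_iterations=2))
        expected = cohort["event_type"].isin(("MI", "HF", "LTVA")).sum()
        assert out["pooled"].n_events == expected
        assert list(out["table"]["category"]) == ["0", "1-5", "6-10", "11-20", ">20"]
        ref = out["table"].iloc[0]
        assert ref["hr"] == 1.0 and np.isfinite(ref["floated_lo"])

    def test_combined_exposure_is_conjunction(self, cohort):
        out = run_analysis(
            cohort,
            AnalysisConfig(exposure="combined_high_burden", covariate_set="minimal", m_imputations=2, mice_iterations=2),
        )
        n_flagged = int(
            ((cohort["exercise_category"] == ">20") & (cohort["recovery_category"] == ">5")).sum()
        )
        assert out["table"].iloc[1]["n"] == n_flagged

    def test_exclusions_reduce_n(self, cohort):
        out = run_analysis(
            cohort,
            AnalysisConfig(covariate_set="minimal", exclusions=("copd", "ckd"), m_imputations=2, mice_iterations=2),
        )
        flagged = int(((cohort["copd"] == 1) | (cohort["ckd"] == 1)).sum())
        assert out["manifest"]["n_excluded"] == flagged

    def test_resting_pvc_adjustment_leaves_recovery_intact(self, cohort):
        base = run_analysis(cohort, AnalysisConfig(covariate_set="minimal", m_imputations=2, mice_iterations=2, seed=1))
        adj = run_analysis(
            cohort,
            AnalysisConfig(covariate_set="minimal", adjust_resting_pvc=True, m_imputations=2, mice_iterations=2, seed=1),
        )
        # resting PVC status is independent of exercise burden in the generator
        b0 = base["pooled"].beta.to_numpy()
        b1 = adj["pooled"].beta.to_numpy()
        assert np.all(np.abs(b0 - b1) < 0.5 * base["pooled"].se.to_numpy())
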