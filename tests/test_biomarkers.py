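"""Mixed-model contrasts, signature FDR, ppm replication, variance partition."""

import numpy as np
import pandas as pd
import pytest

from swabomics.biomarkers import (
    contrast_vector,
    estimate_contrast,
    fdr_correct_signature,
    fit_feature_lmm,
    immune_metabolite_lms,
    lmm_variance_explained,
    match_features_ppm,
    permanova_sequential,
    _grid_vector,
)
from swabomics.containers import FeatureMatrix, LDOM_CSTS
from swabomics.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="module")
def recovery_cohort():
    """Cohort with a known LDEPL offset of 1.0 and modest noise."""
    cfg = CohortConfig(
        n_subjects=200, visits_per_subject=3, seed=21, n_features=3,
        noise_sd=0.3, subject_sd_intercept=0.3, subject_sd_slope=0.01,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def recovery_fit(recovery_cohort):
    col = recovery_cohort.metabolome.values.columns[0]
    return fit_feature_lmm(
        recovery_cohort.metabolome.values[col], recovery_cohort.covariates
    )


class TestLmmFit:
    def test_known_offset_recovered(self, recovery_cohort, recovery_fit):
        r = estimate_contrast(recovery_fit, "LDOM_vs_LDEPL")
        # true LDOM - LDEPL log-intensity difference is -1.0
        assert abs(r.estimate - (-1.0)) < 3 * r.se

    def test_null_slope_not_significant(self):
        cfg = CohortConfig(
            n_subjects=150, visits_per_subject=3, seed=22, n_features=3,
            noise_sd=0.3, subject_sd_intercept=0.3, subject_sd_slope=0.01,
        )
        cfg.effect_table["ga_slope"] = 0.0
        cohort = generate_cohort(cfg)
        for col in cohort.metabolome.values.columns[:2]:
            fit = fit_feature_lmm(cohort.metabolome.values[col], cohort.covariates)
            r = estimate_contrast(fit, "early_vs_late_gestation")
            assert abs(r.estimate / r.se) < 5

    def test_constant_response(self, recovery_cohort):
        y = pd.Series(
            3.0, index=recovery_cohort.covariates.index, name=100.0
        )
        fit = fit_feature_lmm(y, recovery_cohort.covariates)
        assert fit.constant_response
        r = estimate_contrast(fit, "CSTI_vs_III")
        assert r.estimate == 0.0 and r.p == 1.0


class TestContrasts:
    def test_ldom_ldepl_equals_direct_grid_computation(self, recovery_fit):
        beta = np.asarray(recovery_fit.result.fe_params)
        ldom = [c for c in recovery_fit.cst_levels if c in LDOM_CSTS]
        direct = np.mean(
            [float(_grid_vector(recovery_fit, c) @ beta) for c in ldom]
        ) - float(_grid_vector(recovery_fit, "IV") @ beta)
        r = estimate_contrast(recovery_fit, "LDOM_vs_LDEPL")
        assert r.estimate == pytest.approx(direct, rel=1e-10)

    def test_gestation_contrast_is_scaled_slope(self, recovery_fit):
        beta = np.asarray(recovery_fit.result.fe_params)
        ix = recovery_fit.fe_names.index("gestational_age")
        r = estimate_contrast(recovery_fit, "early_vs_late_gestation")
        assert r.estimate == pytest.approx(20.0 * beta[ix], rel=1e-10)

    def test_absent_level_errors(self, recovery_cohort):
        cov = recovery_cohort.covariates.copy()
        keep = cov["cst"] != "IV"
        col = recovery_cohort.metabolome.values.columns[0]
        fit = fit_feature_lmm(
            recovery_cohort.metabolome.values.loc[keep, col], cov.loc[keep]
        )
        with pytest.raises(ValueError, match="IV"):
            estimate_contrast(fit, "CSTI_vs_IV")

    def test_shift_invariance(self, recovery_cohort, recovery_fit):
        col = recovery_cohort.metabolome.values.columns[0]
        shifted = recovery_cohort.metabolome.values[col] + 7.5
        fit2 = fit_feature_lmm(shifted, recovery_cohort.covariates)
        r1 = estimate_contrast(recovery_fit, "LDOM_vs_LDEPL")
        r2 = estimate_contrast(fit2, "LDOM_vs_LDEPL")
        assert r2.estimate == pytest.approx(r1.estimate, abs=1e-6)


class TestFdr:
    def test_bh_by_hand(self):
        q = fdr_correct_signature(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        q = fdr_correct_signature(np.ones(10))
        assert (q == 1.0).all()

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = fdr_correct_signature(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fdr_correct_signature(np.array([0.5, 1.5]))


class TestPpmMatching:
    def _sig(self, mzs, qs):
        return pd.DataFrame({"feature_mz": mzs, "q": qs})

    def test_within_and_beyond_tolerance(self):
        a = self._sig([500.0000], [0.01])
        b_close = self._sig([500.0024], [0.01])
        b_far = self._sig([500.0030], [0.01])
        assert len(match_features_ppm(a, b_close)) == 1
        assert match_features_ppm(a, b_close)["replicated"].all()
        assert len(match_features_ppm(a, b_far)) == 0

    def test_replication_requires_both_q(self):
        a = self._sig([400.0], [0.01])
        b = self._sig([400.0001], [0.2])
        out = match_features_ppm(a, b)
        assert len(out) == 1 and not out["replicated"].iloc[0]

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        mz = np.sort(rng.uniform(100, 900, 30))
        a = self._sig(mz, rng.uniform(0, 0.04, 30))
        b = self._sig(mz * (1 + rng.normal(0, 1e-6, 30)),
                      rng.uniform(0, 0.04, 30))
        ab = match_features_ppm(a, b)
        ba = match_features_ppm(b, a)
        assert ab["replicated"].sum() == ba["replicated"].sum()


class TestVarianceExplained:
    def test_cst_dominated_feature(self):
        cfg = CohortConfig(
            n_subjects=150, visits_per_subject=3, seed=31, n_features=2,
            noise_sd=0.05, subject_sd_intercept=0.0, subject_sd_slope=0.0,
        )
        eff = cfg.effect_table
        eff.loc[:, [c for c in eff.columns if c.startswith("cst_")]] = 0.0
        for c in ("cst_IV", "cst_VI"):
            eff[c] = 3.0
        eff["ga_slope"] = 0.0
        cohort = generate_cohort(cfg)
        col = cohort.metabolome.values.columns[0]
        fit = fit_feature_lmm(cohort.metabolome.values[col], cohort.covariates)
        rep = lmm_variance_explained(fit)
        assert rep["semi_partial"]["cst"] > 0.9
        for term in ("gestational_age", "bmi", "maternal_age", "ethnicity"):
            assert rep["semi_partial"][term] < 0.05

    def test_pure_noise_feature(self):
        cfg = CohortConfig(
            n_subjects=200, visits_per_subject=3, seed=32, n_features=35,
            subject_sd_intercept=0.0, subject_sd_slope=0.0,
        )
        cohort = generate_cohort(cfg)
        col = cohort.metabolome.values.columns[-1]  # null feature
        fit = fit_feature_lmm(cohort.metabolome.values[col], cohort.covariates)
        rep = lmm_variance_explained(fit)
        assert rep["conditional_r2"] < 0.1

    def test_conditional_bounds(self, recovery_fit):
        rep = lmm_variance_explained(recovery_fit)
        assert 0.0 <= rep["conditional_r2"] <= 1.0


class TestPermanova:
    def _toy(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame(
            {
                "cst": rng.choice(["I", "III", "IV"], n),
                "gestational_age": rng.uniform(10, 35, n),
                "ethnicity": rng.choice(["a", "b"], n),
                "bmi": rng.uniform(18, 35, n),
                "maternal_age": rng.uniform(20, 42, n),
                "subject_id": [f"P{i // 2}" for i in range(n)],
            },
            index=[f"s{i}" for i in range(n)],
        )
        Y = pd.DataFrame(rng.uniform(0, 5, (n, 4)), index=cov.index,
                         columns=[100.0, 200.0, 300.0, 400.0])
        return Y, cov

    def test_cst_determined_response_r2_one(self):
        Y, cov = self._toy()
        means = {"I": 1.0, "III": 4.0, "IV": 9.0}
        Y.loc[:, :] = np.array([[means[c]] * 4 for c in cov["cst"]])
        rep = permanova_sequential(Y, cov, terms=("cst", "gestational_age"),
                                   n_perm=49, seed=0, log_transform=True)
        assert rep.loc["cst", "r2"] == pytest.approx(1.0, abs=1e-9)

    def test_r2_partition_sums_to_one(self):
        Y, cov = self._toy(seed=3)
        rep = permanova_sequential(Y, cov, n_perm=49, seed=1)
        terms = [t for t in rep.index if t not in ("Total",)]
        assert rep.loc[terms, "r2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_level_term_na(self):
        Y, cov = self._toy(seed=4)
        cov["ethnicity"] = "a"
        rep = permanova_sequential(Y, cov, n_perm=49, seed=2)
        assert rep.loc["ethnicity", "ss"] == 0.0
        assert np.isnan(rep.loc["ethnicity", "p"])


class TestImmuneAssociations:
    def test_exact_linear_pair(self, small_cohort):
        matrix = small_cohort.metabolome
        marker = np.expm1(matrix.values.iloc[:, 0])
        immune = pd.DataFrame({"M": np.clip(marker, 0, None)},
                              index=matrix.sample_ids)
        out = immune_metabolite_lms(immune, matrix)
        top = out[out["feature_mz"] == float(matrix.values.columns[0])]
        assert top["r2"].iloc[0] > 0.999
        assert top["q"].iloc[0] < 1e-10

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        n = 400
        idx = [f"s{i}" for i in range(n)]
        feats = pd.DataFrame(rng.normal(size=(n, 500)), index=idx,
                             columns=np.linspace(100, 900, 500))
        matrix = FeatureMatrix(values=feats)
        immune = pd.DataFrame({"M": rng.uniform(0, 10, n)}, index=idx)
        out = immune_metabolite_lms(immune, matrix)
        from scipy.stats import kstest
        assert kstest(out["p"], "uniform").pvalue > 0.01

    def test_t_sign_matches_slope(self, small_cohort):
        matrix = small_cohort.metabolome
        out = immune_metabolite_lms(small_cohort.immune, matrix)
        ok = out.dropna(subset=["t", "slope"])
        assert (np.sign(ok["t"]) == np.sign(ok["slope"])).all()

    def test_constant_feature_flagged(self, small_cohort):
        vals = small_cohort.metabolome.values.copy()
        vals.iloc[:, 0] = 1.0
        matrix = FeatureMatrix(values=vals, log_scale=True)
        out = immune_metabolite_lms(small_cohort.immune, matrix)
        flagged = out[out["feature_mz"] == float(vals.columns[0])]
        assert flagged["constant_feature"].all()
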