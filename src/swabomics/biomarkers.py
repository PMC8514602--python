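"""Per-feature mixed-model biomarker discovery and variance partitioning.

Each metabolite feature (log intensity) is modelled with a linear mixed
model::

    Metabolite ~ GestationalAge + CST + MaternalAge + BMI + Ethnicity
                 + (GestationalAge || SubjectID)

i.e. fixed effects for gestational age, community state type and
demographics, plus *uncorrelated* per-pregnancy random intercepts and random
gestational-age slopes, fitted by REML.  Contrasts of interest (CST pairs,
Lactobacillus dominated vs depleted, early vs late gestation) are estimated
on a reference grid (maternal age 30 y, BMI 23 kg/m2, gestational age 20
weeks, unweighted average over ethnicity levels) and tested with a
t-statistic whose denominator degrees of freedom use the Satterthwaite
small-sample approximation.  Per-contrast p-values are pooled across all
features of an assay and Benjamini-Hochberg corrected as one signature;
features replicate across cohorts when matched within a ppm m/z tolerance
with q < 0.05 on both sides.  Variance is partitioned per feature
(semi-partial R2 per fixed term, conditional R2) and across the matrix by
sequential-sum-of-squares PERMANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from swabomics.containers import ALL_CSTS, FeatureMatrix, LDOM_CSTS

CONTRASTS = (
    "LDOM_vs_LDEPL",
    "CSTI_vs_III",
    "CSTI_vs_IV",
    "CSTIII_vs_IV",
    "early_vs_late_gestation",
)

#: reference grid for contrast estimation
GRID_MATERNAL_AGE = 30.0
GRID_BMI = 23.0
GRID_GESTATIONAL_AGE = 20.0
#: week span represented by the early-vs-late gestation contrast
GESTATION_CONTRAST_WEEKS = 20.0


@dataclass
class FeatureFit:
    """A fitted per-feature mixed model plus the design bookkeeping needed
    for contrasts and Satterthwaite degrees of freedom."""

    result: object
    feature_mz: float
    fe_names: list[str]
    cst_levels: list[str]
    ethnicity_levels: list[str]
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    ga: np.ndarray
    has_random_slope: bool
    singular: bool = False
    constant_response: bool = False


@dataclass
class ContrastResult:
    feature_mz: float
    contrast: str
    estimate: float
    se: float
    p: float
    df: float = np.nan
    q: float = np.nan


def fit_feature_lmm(feature_values: pd.Series, covariates: pd.DataFrame) -> FeatureFit:
    """REML fit of the per-feature mixed model.

    Random effects are an intercept and a gestational-age slope per subject,
    modelled as independent (diagonal covariance).  A singular fit (random
    slope variance collapsing to the boundary or non-convergence) triggers a
    refit without the random slope, flagged on the returned object.
    """
    cov = covariates.loc[feature_values.index]
    y = feature_values.to_numpy(dtype=float)
    groups = cov["subject_id"].to_numpy()
    ga = cov["gestational_age"].to_numpy(dtype=float)
    mz = float(feature_values.name) if feature_values.name is not None else np.nan
    cst_levels = [c for c in ALL_CSTS if c in set(cov["cst"])]
    eth_levels = sorted(set(cov["ethnicity"]))

    df = pd.DataFrame(
        {
            "y": y,
            "gestational_age": ga,
            "cst": pd.Categorical(cov["cst"], categories=cst_levels),
            "maternal_age": cov["maternal_age"].to_numpy(dtype=float),
            "bmi": cov["bmi"].to_numpy(dtype=float),
            "ethnicity": pd.Categorical(cov["ethnicity"], categories=eth_levels),
            "subject_id": groups,
        },
        index=cov.index,
    )
    formula = "y ~ gestational_age + cst + maternal_age + bmi"
    if len(eth_levels) > 1:
        formula += " + ethnicity"

    if np.ptp(y) == 0:
        return FeatureFit(
            result=None, feature_mz=mz, fe_names=[],
            cst_levels=cst_levels, ethnicity_levels=eth_levels,
            X=np.empty((len(y), 0)), y=y, groups=groups, ga=ga,
            has_random_slope=False, constant_response=True,
        )

    def _fit(with_slope: bool):
        kwargs = {"groups": "subject_id", "re_formula": "1"}
        if with_slope:
            kwargs["vc_formula"] = {"ga_slope": "0 + gestational_age"}
        model = MixedLM.from_formula(formula, data=df, **kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True, method=["lbfgs", "cg", "powell"], maxiter=200)
        return model, res

    singular = False
    has_slope = True
    try:
        model, res = _fit(with_slope=True)
        vc = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        if not res.converged or vc < 1e-10 * max(res.scale, 1e-12):
            raise RuntimeError("singular or non-converged random slope")
    except Exception:
        singular = True
        has_slope = False
        model, res = _fit(with_slope=False)
    return FeatureFit(
        result=res, feature_mz=mz, fe_names=list(model.exog_names),
        cst_levels=cst_levels, ethnicity_levels=eth_levels,
        X=np.asarray(model.exog, dtype=float), y=y, groups=groups, ga=ga,
        has_random_slope=has_slope, singular=singular,
    )


def _dummy_index(fe_names: list[str], factor: str, level: str) -> int | None:
    """Locate the treatment-coded dummy column for ``factor`` at ``level``."""
    tag = f"[T.{level}]"
    for i, name in enumerate(fe_names):
        if factor in name and name.endswith(tag):
            return i
    return None


# ---------------------------------------------------------------------------
# contrasts on the reference grid


def _grid_vector(fit: FeatureFit, cst: str) -> np.ndarray:
    """Fixed-effect coefficient vector of the reference-grid prediction for
    one CST (maternal age 30, BMI 23, GA 20 weeks, ethnicity averaged)."""
    if cst not in fit.cst_levels:
        raise ValueError(f"contrast references absent CST level: {cst}")
    v = np.zeros(len(fit.fe_names))
    name_ix = {n: i for i, n in enumerate(fit.fe_names)}
    v[name_ix["Intercept"]] = 1.0
    v[name_ix["gestational_age"]] = GRID_GESTATIONAL_AGE
    v[name_ix["maternal_age"]] = GRID_MATERNAL_AGE
    v[name_ix["bmi"]] = GRID_BMI
    ci = _dummy_index(fit.fe_names, "cst", cst)
    if ci is not None:
        v[ci] = 1.0
    n_eth = len(fit.ethnicity_levels)
    for lev in fit.ethnicity_levels[1:]:
        ei = _dummy_index(fit.fe_names, "ethnicity", lev)
        if ei is not None:
            v[ei] = 1.0 / n_eth
    return v


def contrast_vector(fit: FeatureFit, contrast: str) -> np.ndarray:
    """Linear combination of fixed effects realising a named contrast."""
    name_ix = {n: i for i, n in enumerate(fit.fe_names)}
    if contrast == "LDOM_vs_LDEPL":
        ldom = [c for c in fit.cst_levels if c in LDOM_CSTS]
        if not ldom:
            raise ValueError("contrast references absent CST levels: LDOM set")
        c = np.zeros(len(fit.fe_names))
        for lev in ldom:
            c += _grid_vector(fit, lev) / len(ldom)
        c -= _grid_vector(fit, "IV")
        return c
    if contrast == "CSTI_vs_III":
        return _grid_vector(fit, "I") - _grid_vector(fit, "III")
    if contrast == "CSTI_vs_IV":
        return _grid_vector(fit, "I") - _grid_vector(fit, "IV")
    if contrast == "CSTIII_vs_IV":
        return _grid_vector(fit, "III") - _grid_vector(fit, "IV")
    if contrast == "early_vs_late_gestation":
        c = np.zeros(len(fit.fe_names))
        c[name_ix["gestational_age"]] = GESTATION_CONTRAST_WEEKS
        return c
    raise ValueError(f"unknown contrast {contrast!r}")


def _reml_theta(fit: FeatureFit):
    """Variance parameters (intercept var, slope var, residual var)."""
    res = fit.result
    s_u = float(np.asarray(res.cov_re).ravel()[0]) if res.k_re else 0.0
    s_v = float(res.vcomp[0]) if fit.has_random_slope and len(res.vcomp) else 0.0
    return np.array([s_u, s_v, float(res.scale)])


def _per_subject(fit: FeatureFit):
    blocks = []
    for g in pd.unique(fit.groups):
        ix = fit.groups == g
        blocks.append((fit.X[ix], fit.y[ix], fit.ga[ix]))
    return blocks


def _xtvix_and_reml(theta, blocks, with_slope: bool):
    """Return (X'V^-1X, REML log-likelihood up to a constant) at theta."""
    s_u, s_v, s_e = np.maximum(theta, 1e-12)
    p = blocks[0][0].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet_v = 0.0
    yvy = 0.0
    for Xi, yi, gai in blocks:
        ni = len(yi)
        Vi = s_e * np.eye(ni) + s_u
        if with_slope:
            Vi = Vi + s_v * np.outer(gai, gai)
        sign, ld = np.linalg.slogdet(Vi)
        logdet_v += ld
        Vinv_X = np.linalg.solve(Vi, Xi)
        Vinv_y = np.linalg.solve(Vi, yi)
        xtvx += Xi.T @ Vinv_X
        xtvy += Xi.T @ Vinv_y
        yvy += yi @ Vinv_y
    beta = np.linalg.solve(xtvx, xtvy)
    rss = yvy - xtvy @ beta
    sign2, ld2 = np.linalg.slogdet(xtvx)
    loglike = -0.5 * (logdet_v + ld2 + rss)
    return xtvx, loglike


def _satterthwaite_df(fit: FeatureFit, c: np.ndarray) -> float:
    """Satterthwaite denominator df for the contrast c'beta.

    df = 2 var_c^2 / (g' W g), where var_c(theta) = c'(X'V^-1X)^-1 c,
    g its gradient in the variance parameters and W the inverse negative
    Hessian of the REML log-likelihood.  Falls back to residual df when the
    curvature is degenerate (e.g. a variance at the boundary).
    """
    blocks = _per_subject(fit)
    with_slope = fit.has_random_slope
    theta = _reml_theta(fit)
    active = [0, 2] if not with_slope else [0, 1, 2]
    th_act = theta[active]

    def var_c(ta):
        full = theta.copy()
        full[active] = ta
        xtvx, _ = _xtvix_and_reml(full, blocks, with_slope)
        return float(c @ np.linalg.solve(xtvx, c))

    def reml(ta):
        full = theta.copy()
        full[active] = ta
        _, ll = _xtvix_and_reml(full, blocks, with_slope)
        return ll

    n, p = fit.X.shape
    resid_df = max(n - p, 1.0)
    try:
        h = np.maximum(np.abs(th_act), 1e-8) * 1e-4
        k = len(th_act)
        grad = np.zeros(k)
        v0 = var_c(th_act)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            grad[i] = (var_c(th_act + e) - var_c(th_act - e)) / (2 * h[i])
        H = np.zeros((k, k))
        f0 = reml(th_act)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            for j in range(i, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                fpp = reml(th_act + ei + ej)
                fpm = reml(th_act + ei - ej)
                fmp = reml(th_act - ei + ej)
                fmm = reml(th_act - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        W = np.linalg.pinv(-H)
        denom = float(grad @ W @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return resid_df
        df = 2.0 * v0**2 / denom
        if not np.isfinite(df) or df < 1.0:
            return resid_df
        return float(min(df, resid_df))
    except np.linalg.LinAlgError:
        return resid_df


def estimate_contrast(fit: FeatureFit, contrast: str) -> ContrastResult:
    """Estimate a named contrast with a Satterthwaite-df t-test."""
    if fit.constant_response:
        return ContrastResult(fit.feature_mz, contrast, 0.0, 0.0, 1.0)
    c = contrast_vector(fit, contrast)
    res = fit.result
    beta = np.asarray(res.fe_params)
    est = float(c @ beta)
    cov = np.asarray(res.cov_params())[: len(beta), : len(beta)]
    var = float(c @ cov @ c)
    if not np.isfinite(var) or var < 0:
        # non-PSD covariance from a degenerate fit: rebuild the fixed-effect
        # covariance as (X'V^-1 X)^-1 at the REML variance estimates
        try:
            xtvx, _ = _xtvix_and_reml(
                _reml_theta(fit), _per_subject(fit), fit.has_random_slope
            )
            var = float(c @ np.linalg.solve(xtvx, c))
        except np.linalg.LinAlgError:
            var = np.nan
        if not np.isfinite(var) or var <= 0:
            return ContrastResult(fit.feature_mz, contrast, est, np.nan, 1.0)
    se = float(np.sqrt(var))
    if se == 0:
        return ContrastResult(fit.feature_mz, contrast, est, 0.0, 1.0)
    df = _satterthwaite_df(fit, c)
    t = est / se
    p = float(2 * stats.t.sf(abs(t), df))
    return ContrastResult(fit.feature_mz, contrast, est, se, p, df=df)


def discover_biomarkers(
    matrix: FeatureMatrix,
    covariates: pd.DataFrame,
    contrasts: tuple[str, ...] = CONTRASTS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every feature, estimate the named contrasts and FDR-correct each
    contrast as one signature.  Returns a tidy frame (feature_mz, contrast,
    estimate, se, p, q, df, singular)."""
    rows = []
    for col in matrix.values.columns:
        fit = fit_feature_lmm(matrix.values[col], covariates)
        for name in contrasts:
            r = estimate_contrast(fit, name)
            rows.append(
                {
                    "feature_mz": r.feature_mz, "contrast": name,
                    "estimate": r.estimate, "se": r.se, "p": r.p, "df": r.df,
                    "singular": fit.singular,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for name in contrasts:
        mask = out["contrast"] == name
        out.loc[mask, "q"] = fdr_correct_signature(out.loc[mask, "p"].to_numpy(), alpha)
    return out


def fdr_correct_signature(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one signature."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q


def match_features_ppm(
    signature_a: pd.DataFrame,
    signature_b: pd.DataFrame,
    ppm: float = 5.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-cohort replication by ppm m/z matching.

    Each feature of signature A is matched to the nearest feature of
    signature B with |mz_a - mz_b| / mz_a * 1e6 < ppm.  A pair replicates
    iff matched and q < ``alpha`` on both sides.  Signatures are frames with
    ``feature_mz`` and ``q`` columns.
    """
    mz_b = signature_b["feature_mz"].to_numpy(dtype=float)
    order = np.argsort(mz_b)
    mz_b_sorted = mz_b[order]
    rows = []
    for _, row in signature_a.iterrows():
        mz_a = float(row["feature_mz"])
        if mz_b_sorted.size == 0:
            continue
        pos = np.searchsorted(mz_b_sorted, mz_a)
        cand = [i for i in (pos - 1, pos) if 0 <= i < mz_b_sorted.size]
        best = min(cand, key=lambda i: abs(mz_b_sorted[i] - mz_a))
        err_ppm = abs(mz_a - mz_b_sorted[best]) / mz_a * 1e6
        if err_ppm >= ppm:
            continue
        j = order[best]
        q_a = float(row["q"])
        q_b = float(signature_b["q"].iloc[j])
        rows.append(
            {
                "mz_A": mz_a, "mz_B": float(mz_b[j]), "ppm_error": err_ppm,
                "q_A": q_a, "q_B": q_b,
                "replicated": bool(q_a < alpha and q_b < alpha),
            }
        )
    return pd.DataFrame(
        rows, columns=["mz_A", "mz_B", "ppm_error", "q_A", "q_B", "replicated"]
    )


# ---------------------------------------------------------------------------
# variance explained


def lmm_variance_explained(fit: FeatureFit) -> dict:
    """Semi-partial R2 per fixed-effect term and conditional R2.

    Semi-partial R2 uses the Wald standardized-effect formulation
    R2_t = q F_t / (q F_t + nu) with nu the residual degrees of freedom;
    conditional R2 is the variance of fixed-plus-random predictions over the
    total response variance.
    """
    if fit.constant_response:
        terms = ["cst", "gestational_age", "ethnicity", "bmi", "maternal_age"]
        return {"semi_partial": {t: 0.0 for t in terms}, "conditional_r2": 0.0}
    res = fit.result
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(beta), : len(beta)]
    n, p = fit.X.shape
    nu = max(n - p, 1)
    term_cols = {
        "gestational_age": [i for i, nme in enumerate(fit.fe_names) if nme == "gestational_age"],
        "cst": [i for i, nme in enumerate(fit.fe_names) if nme.startswith("cst[")],
        "maternal_age": [i for i, nme in enumerate(fit.fe_names) if nme == "maternal_age"],
        "bmi": [i for i, nme in enumerate(fit.fe_names) if nme == "bmi"],
        "ethnicity": [i for i, nme in enumerate(fit.fe_names) if nme.startswith("ethnicity[")],
    }
    semi = {}
    for term, cols in term_cols.items():
        if not cols:
            semi[term] = 0.0
            continue
        b = beta[cols]
        S = cov[np.ix_(cols, cols)]
        try:
            wald = float(b @ np.linalg.solve(S, b))
        except np.linalg.LinAlgError:
            semi[term] = 0.0
            continue
        q = len(cols)
        F = wald / q
        semi[term] = float(q * F / (q * F + nu))

    total_var = float(np.var(fit.y))
    if total_var == 0:
        return {"semi_partial": semi, "conditional_r2": 0.0}
    pred = fit.X @ beta
    re = res.random_effects
    ix = 0
    pred_re = pred.copy()
    for g in pd.unique(fit.groups):
        sel = fit.groups == g
        re_g = np.asarray(re[g], dtype=float).ravel()
        pred_re[sel] += re_g[0]
        if fit.has_random_slope and re_g.size > 1:
            pred_re[sel] += re_g[1] * fit.ga[sel]
        ix += 1
    cond = float(np.var(pred_re) / total_var)
    return {"semi_partial": semi, "conditional_r2": min(cond, 1.0)}


# ---------------------------------------------------------------------------
# sequential PERMANOVA


PERMANOVA_TERMS = ("cst", "gestational_age", "ethnicity", "bmi", "maternal_age", "subject_id")


def permanova_sequential(
    matrix: FeatureMatrix | pd.DataFrame,
    covariates: pd.DataFrame,
    terms: tuple[str, ...] = PERMANOVA_TERMS,
    n_perm: int = 999,
    seed: int = 0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Sequential (type-I) PERMANOVA with Euclidean response geometry.

    The response is log(values + 1); with Euclidean distances the analysis
    reduces exactly to sequential multivariate regression sums of squares,
    computed by incremental orthogonalisation of the term design blocks.
    Pseudo-F per term uses the full-model residual; p-values come from free
    permutation of response rows: p = (#{F_perm >= F_obs} + 1)/(n_perm + 1).
    Terms with a single level get SS = 0 and p = NA.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    cov = covariates.loc[values.index]
    Y = values.to_numpy(dtype=float)
    if log_transform:
        Y = np.log1p(Y)
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())
    if ss_total == 0:
        raise ValueError("response matrix has zero total variance")

    # sequential orthonormal block per term
    basis = np.ones((n, 1)) / np.sqrt(n)
    blocks: list[tuple[str, np.ndarray, int]] = []
    for term in terms:
        col = cov[term]
        if col.dtype.kind in "OUSb" or term in ("cst", "ethnicity", "subject_id"):
            levels = pd.unique(col)
            if len(levels) < 2:
                blocks.append((term, np.zeros((n, 0)), 0))
                continue
            D = np.column_stack([(col == lev).to_numpy(float) for lev in levels[1:]])
        else:
            x = col.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                blocks.append((term, np.zeros((n, 0)), 0))
                continue
            D = x[:, None]
        # project out everything fitted so far, then orthonormalise
        R = D - basis @ (basis.T @ D)
        Q, Rr = np.linalg.qr(R)
        keep = np.abs(np.diag(Rr)) > 1e-8 * max(1.0, np.abs(Rr).max())
        Q = Q[:, keep]
        blocks.append((term, Q, Q.shape[1]))
        if Q.shape[1]:
            basis = np.column_stack([basis, Q])

    df_model = sum(df for _, _, df in blocks)
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_ss(Yp):
        return np.array([
            float(((Q.T @ Yp) ** 2).sum()) if df else 0.0 for _, Q, df in blocks
        ])

    ss_obs = term_ss(Yc)
    ss_res = ss_total - ss_obs.sum()
    dfs = np.array([df for _, _, df in blocks], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = np.where(dfs > 0, (ss_obs / np.where(dfs > 0, dfs, 1)) / (ss_res / df_res), np.nan)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(blocks))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Yc[perm]
        ssp = term_ss(Yp)
        ssr = ss_total - ssp.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            fp = np.where(dfs > 0, (ssp / np.where(dfs > 0, dfs, 1)) / (ssr / df_res), np.nan)
        exceed += (fp >= f_obs - 1e-12) & (dfs > 0)
    p = np.where(dfs > 0, (exceed + 1) / (n_perm + 1), np.nan)

    out = pd.DataFrame(
        {
            "term": [t for t, _, _ in blocks],
            "df": dfs.astype(int),
            "ss": ss_obs,
            "r2": ss_obs / ss_total,
            "pseudo_F": f_obs,
            "p": p,
        }
    ).set_index("term")
    out.loc["Residual"] = [df_res, ss_res, ss_res / ss_total, np.nan, np.nan]
    out.loc["Total"] = [n - 1, ss_total, 1.0, np.nan, np.nan]
    return out


# ---------------------------------------------------------------------------
# immune-metabolite simple regressions


def immune_metabolite_lms(
    immune: pd.DataFrame,
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    r2_filter: float = 0.1,
) -> pd.DataFrame:
    """Per marker x feature simple regression log(marker + 1) ~ feature.

    Returns slope, t-ratio, F-test p, R2 and BH q (corrected within each
    marker independently), plus a boolean applying the R2 > ``r2_filter``
    selection rule.  Constant features are skipped and flagged.
    """
    shared = immune.index.intersection(matrix.sample_ids)
    if shared.empty:
        raise ValueError("no shared samples between immune panel and matrix")
    Ylog = np.log1p(immune.loc[shared].to_numpy(dtype=float))
    X = matrix.values.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    rows = []
    for m_ix, marker in enumerate(immune.columns):
        y = Ylog[:, m_ix]
        yc = y - y.mean()
        for f_ix, mz in enumerate(matrix.values.columns):
            x = X[:, f_ix]
            if np.ptp(x) == 0:
                rows.append(
                    {"marker": marker, "feature_mz": float(mz), "slope": np.nan,
                     "t": np.nan, "p": np.nan, "r2": np.nan, "constant_feature": True}
                )
                continue
            xc = x - x.mean()
            sxx = float(xc @ xc)
            slope = float(xc @ yc) / sxx
            resid = yc - slope * xc
            sse = float(resid @ resid)
            sst = float(yc @ yc)
            if sst == 0:
                r2, t, p = 0.0, 0.0, 1.0
            else:
                r2 = 1 - sse / sst
                if sse <= 0:
                    t, p = np.inf, 0.0
                else:
                    se = np.sqrt(sse / (n - 2) / sxx)
                    t = slope / se
                    p = float(stats.f.sf(t**2, 1, n - 2))
            rows.append(
                {"marker": marker, "feature_mz": float(mz), "slope": slope,
                 "t": float(t), "p": p, "r2": float(r2), "constant_feature": False}
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for marker in immune.columns:
        mask = (out["marker"] == marker) & ~out["constant_feature"]
        if mask.any():
            out.loc[mask, "q"] = fdr_correct_signature(out.loc[mask, "p"].to_numpy(), alpha)
    out["selected"] = (out["q"] < alpha) & (out["r2"] > r2_filter)
    return out
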