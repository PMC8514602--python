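"""Outcome-association statistics.

Instability classification of longitudinal microbiome trajectories and the
small-sample association machinery used for pregnancy outcomes: the two-sided
mid-p exact test with odds-ratio confidence interval, Fisher's exact test,
Pearson's chi-squared (with optional Yates continuity correction) and Welch's
unequal-variance t-test.

The mid-p exact test conditions on the margins of a 2x2 table, so the test
statistic follows a hypergeometric distribution under the null; the mid-p
variant assigns half weight to the observed table, making it less
conservative than Fisher's test while retaining near-nominal size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from swabomics.containers import CSTAssignment


@dataclass
class AssociationResult:
    """Result of one association test."""

    statistic_name: str
    estimate: float
    p: float
    ci_level: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    statistic: float | None = None
    df: float | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0 + 1e-12):
            raise ValueError("p-value outside [0, 1]")


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("a 2x2 table is required")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    return t.astype(int)


# ---------------------------------------------------------------------------
# trajectory stability


def classify_stability(assignments: CSTAssignment, covariates: pd.DataFrame) -> pd.Series:
    """Classify each subject's trajectory as stable_LDOM / stable_LDEPL / unstable.

    A subject is *unstable* iff their time-ordered dominance sequence contains
    both LDOM and LDEPL states.  Subjects with a single classified sample are
    excluded (stability is undefined from one observation) with a warning.

    Parameters
    ----------
    assignments
        Per-sample CST/dominance calls.
    covariates
        Must contain ``subject_id`` and ``gestational_age`` columns indexed by
        sample id (used to order each subject's samples in time).
    """
    dom = assignments.dominance.dropna()
    if dom.empty:
        raise ValueError("no classified samples to derive trajectories from")
    cov = covariates.loc[covariates.index.intersection(dom.index)]
    out = {}
    n_single = 0
    for subject, rows in cov.groupby("subject_id"):
        ordered = rows.sort_values("gestational_age").index
        seq = dom.loc[[s for s in ordered if s in dom.index]]
        if len(seq) == 0:
            raise ValueError(f"empty trajectory for subject {subject!r}")
        if len(seq) < 2:
            n_single += 1
            continue
        states = set(seq)
        if states == {"LDOM"}:
            out[subject] = "stable_LDOM"
        elif states == {"LDEPL"}:
            out[subject] = "stable_LDEPL"
        else:
            out[subject] = "unstable"
    if n_single:
        warnings.warn(
            f"{n_single} subject(s) with a single sample excluded from "
            "stability classification",
            stacklevel=2,
        )
    return pd.Series(out, name="stability", dtype=object)


# ---------------------------------------------------------------------------
# exact 2x2 machinery


def _hypergeom_support(table: np.ndarray):
    """Hypergeometric support and pmf for the [0,0] cell given fixed margins."""
    a = int(table[0, 0])
    r1 = int(table[0].sum())
    c1 = int(table[:, 0].sum())
    n = int(table.sum())
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    return a, support, pmf


def midp_exact_or(table, level: float = 0.95, compute_ci: bool = True) -> AssociationResult:
    """Two-sided mid-p exact test and odds-ratio CI for a 2x2 table.

    Conditional on the margins the [0,0] cell is hypergeometric.  The
    one-sided mid-p is P(X > x) + 0.5 P(X = x) (upper) or P(X < x) +
    0.5 P(X = x) (lower); the two-sided p doubles the smaller side, capped at
    one.  The point estimate is the sample cross-product ratio ad/bc; the CI
    inverts the two-sided mid-p over the odds parameter of Fisher's
    noncentral hypergeometric distribution by bisection.
    """
    t = _as_2x2(table)
    a, b = t[0]
    c, d = t[1]
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        return AssociationResult(
            "midp_exact_or", np.nan, 1.0, ci_level=level,
            flags={"degenerate_margin": True},
        )
    x, support, pmf = _hypergeom_support(t)
    upper = pmf[support > x].sum() + 0.5 * pmf[support == x].sum()
    lower = pmf[support < x].sum() + 0.5 * pmf[support == x].sum()
    p = min(1.0, 2.0 * min(lower, upper))
    if b * c == 0:
        est = np.inf if a * d > 0 else np.nan
    else:
        est = (a * d) / (b * c)

    if not compute_ci:
        return AssociationResult(
            "midp_exact_or", float(est), float(p), ci_level=level,
            flags={"sidedness": "two-sided", "method": "mid-p exact"},
        )
    n = int(t.sum())
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())

    def midp_at(log_psi: float) -> float:
        dist = stats.nchypergeom_fisher(n, c1, r1, np.exp(log_psi))
        pm = dist.pmf(support)
        up = pm[support > x].sum() + 0.5 * pm[support == x].sum()
        lo_ = pm[support < x].sum() + 0.5 * pm[support == x].sum()
        return min(1.0, 2.0 * min(lo_, up))

    alpha = 1.0 - level
    lo_bound, hi_bound = _invert_midp_ci(midp_at, x, support, alpha)
    return AssociationResult(
        "midp_exact_or", float(est), float(p),
        ci_level=level, ci_low=lo_bound, ci_high=hi_bound,
        flags={"sidedness": "two-sided", "method": "mid-p exact"},
    )


def _invert_midp_ci(midp_at, x, support, alpha):
    """Bisection bounds of {psi : two-sided mid-p(psi) >= alpha}.

    The two-sided mid-p is unimodal in log(psi); the bracket for each bound
    is anchored at a coarse-grid argmax so each bisection converges to the
    correct crossing.
    """
    grid = np.linspace(-30.0, 30.0, 121)
    vals = [midp_at(g) for g in grid]
    peak = float(grid[int(np.argmax(vals))])
    if max(vals) < alpha:  # pragma: no cover - alpha would have to exceed ~1
        return np.nan, np.nan

    def bisect(side: str) -> float:
        if side == "low":
            if x == support.min():
                return 0.0
            lo, hi = -30.0, peak
            if midp_at(lo) >= alpha:
                return 0.0
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if midp_at(mid) < alpha:
                    lo = mid
                else:
                    hi = mid
            return float(np.exp(0.5 * (lo + hi)))
        else:
            if x == support.max():
                return np.inf
            lo, hi = peak, 30.0
            if midp_at(hi) >= alpha:
                return np.inf
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if midp_at(mid) < alpha:
                    hi = mid
                else:
                    lo = mid
            return float(np.exp(0.5 * (lo + hi)))

    return bisect("low"), bisect("high")


def fisher_exact(table, two_sided_rule: str = "minlike") -> AssociationResult:
    """Fisher's exact test (two-sided) by hypergeometric enumeration.

    With the default ``minlike`` rule the two-sided p sums the
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table (with a small relative
    tolerance for floating-point ties).  The ``doubling`` rule doubles the
    smaller one-sided tail (capped at 1), matching the two-sided
    construction of the mid-p test.
    """
    t = _as_2x2(table)
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        return AssociationResult(
            "fisher_exact", np.nan, 1.0, flags={"degenerate_margin": True}
        )
    x, support, pmf = _hypergeom_support(t)
    if two_sided_rule == "minlike":
        p_obs = pmf[support == x][0]
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif two_sided_rule == "doubling":
        upper = pmf[support >= x].sum()
        lower = pmf[support <= x].sum()
        p = float(2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown two-sided rule {two_sided_rule!r}")
    p = min(1.0, p)
    if p > 1.0 - 1e-9:
        p = 1.0
    a, b = t[0]
    c, d = t[1]
    est = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    return AssociationResult(
        "fisher_exact", float(est), p,
        flags={"sidedness": "two-sided", "rule": two_sided_rule},
    )


def pearson_chi2(table, continuity: bool = False) -> AssociationResult:
    """Pearson's chi-squared test of independence on an r x c table.

    ``continuity`` applies the Yates |O-E|-0.5 adjustment (2x2 tables only).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("an r x c table with r, c >= 2 is required")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    expected = stats.contingency.expected_freq(t)
    if np.any(expected == 0):
        raise ValueError(
            "zero expected cell count; use an exact test (fisher_exact) instead"
        )
    if continuity and t.shape != (2, 2):
        raise ValueError("continuity correction applies to 2x2 tables only")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=continuity)
    return AssociationResult(
        "pearson_chi2", float(stat), float(p), statistic=float(stat),
        df=float(dof), flags={"continuity": continuity, "sidedness": "two-sided"},
    )


def welch_t(x, y, level: float = 0.95) -> AssociationResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return AssociationResult(
                "welch_t", 0.0, 1.0, statistic=0.0, flags={"zero_variance": True}
            )
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    est = float(np.mean(x) - np.mean(y))
    ci = res.confidence_interval(confidence_level=level)
    return AssociationResult(
        "welch_t", est, float(res.pvalue),
        ci_level=level, ci_low=float(ci.low), ci_high=float(ci.high),
        statistic=float(res.statistic), df=float(res.df),
        flags={"sidedness": "two-sided"},
    )


# ---------------------------------------------------------------------------
# elevated-marker contingency assembly


def elevated_marker_table(
    values: pd.DataFrame,
    group: pd.Series,
    rule: str = "auto",
) -> pd.DataFrame:
    """Assemble an "increased vs not" 2 x k contingency table per group.

    ``values`` is per-subject: either paired columns ``pre``/``post`` (default
    rule: increased iff post > pre) or a single ``value`` column (increased
    iff value > cohort median).  ``rule`` may force "paired" or "median".
    Returns a DataFrame with rows ["increased", "not_increased"] and one
    column per group level.
    """
    if rule == "auto":
        rule = "paired" if {"pre", "post"} <= set(values.columns) else "median"
    if rule == "paired":
        if not {"pre", "post"} <= set(values.columns):
            raise ValueError("paired rule requires 'pre' and 'post' columns")
        increased = values["post"] > values["pre"]
    elif rule == "median":
        if "value" not in values.columns:
            raise ValueError("median rule requires a 'value' column")
        increased = values["value"] > values["value"].median()
    else:
        raise ValueError(f"unknown rule {rule!r}")
    group = group.reindex(values.index)
    levels = pd.unique(group.dropna())
    table = pd.DataFrame(
        0, index=["increased", "not_increased"], columns=list(levels), dtype=int
    )
    for lev in levels:
        mask = group == lev
        table.loc["increased", lev] = int(increased[mask].sum())
        table.loc["not_increased", lev] = int((~increased[mask]).sum())
    return table
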