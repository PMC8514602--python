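"""Screening of cultured bacterial isolates against media background.

Replicate on-swab intensity profiles of a cultured isolate are compared per
m/z feature against matched culture-media background swabs with the exact
two-sided Wilcoxon-Mann-Whitney rank-sum test; effect size is the log2 ratio
of mean biomass to mean background intensity.  Significant features are then
matched to the in vivo discriminatory signature by the same ppm tolerance
rule used for cross-cohort replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from swabomics.biomarkers import fdr_correct_signature, match_features_ppm


@dataclass
class IsolateExperiment:
    """Replicate intensities for one isolate and its media background.

    ``biomass`` and ``background`` are feature x replicate frames sharing a
    feature-m/z index (>= 3 replicates each).
    """

    isolate_id: str
    species: str
    biomass: pd.DataFrame
    background: pd.DataFrame
    media: str = ""

    def __post_init__(self) -> None:
        if not self.biomass.index.equals(self.background.index):
            raise ValueError("biomass and background must share the feature axis")
        if self.biomass.shape[1] < 3 or self.background.shape[1] < 3:
            raise ValueError("need at least three replicates per side")


def screen_isolate(exp: IsolateExperiment) -> pd.DataFrame:
    """Per-feature exact two-sided rank-sum p-values (biomass vs background).

    All-tied features get p = 1 with a flag.  The test is exact (no
    continuity correction) for the small replicate numbers typical here.
    """
    rows = []
    for mz in exp.biomass.index:
        x = exp.biomass.loc[mz].to_numpy(dtype=float)
        y = exp.background.loc[mz].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append({"feature_mz": float(mz), "p": 1.0, "all_tied": True})
            continue
        try:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            p = float(res.pvalue)
        except ValueError:
            # ties force the normal approximation
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            p = float(res.pvalue)
        rows.append({"feature_mz": float(mz), "p": p, "all_tied": False})
    return pd.DataFrame(rows).set_index("feature_mz")


def fold_change(exp: IsolateExperiment) -> pd.Series:
    """Mean log2 fold change: log2(mean biomass / mean background).

    Undefined (NaN) where the background mean is zero.
    """
    mb = exp.biomass.mean(axis=1).to_numpy(dtype=float)
    mg = exp.background.mean(axis=1).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mg > 0, np.log2(np.where(mg > 0, mb, 1) / np.where(mg > 0, mg, 1)), np.nan)
    return pd.Series(fc, index=exp.biomass.index.astype(float), name="log2_fc")


def match_to_invivo(
    results: pd.DataFrame,
    invivo_signature: pd.DataFrame,
    ppm: float = 5.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Match significant isolate features to the in vivo signature by ppm.

    ``results`` must have a float feature_mz index with columns ``q`` and
    ``log2_fc``; ``invivo_signature`` is a frame with ``feature_mz`` and
    ``q`` (the FDR-corrected in vivo discriminatory features).  Reuses the
    shared ppm matching operation; unmatched significant features are
    reported with ``matched = False``.
    """
    sig = results[results["q"] < alpha]
    if sig.empty:
        return pd.DataFrame(
            columns=["feature_mz", "log2_fc", "invivo_mz", "ppm_error", "matched"]
        )
    as_signature = pd.DataFrame(
        {"feature_mz": sig.index.to_numpy(dtype=float), "q": sig["q"].to_numpy()}
    )
    pairs = match_features_ppm(as_signature, invivo_signature, ppm=ppm, alpha=alpha)
    matched_mz = dict(zip(pairs["mz_A"], zip(pairs["mz_B"], pairs["ppm_error"])))
    rows = []
    for mz, row in sig.iterrows():
        hit = matched_mz.get(float(mz))
        rows.append(
            {
                "feature_mz": float(mz),
                "log2_fc": float(row.get("log2_fc", np.nan)),
                "invivo_mz": hit[0] if hit else np.nan,
                "ppm_error": hit[1] if hit else np.nan,
                "matched": hit is not None,
            }
        )
    return pd.DataFrame(rows)


def screen_and_match(
    exp: IsolateExperiment,
    invivo_signature: pd.DataFrame | None = None,
    ppm: float = 5.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full isolate screen: rank-sum tests, BH correction within the
    isolate, fold changes, and optional matching to the in vivo signature."""
    res = screen_isolate(exp)
    res["q"] = fdr_correct_signature(res["p"].to_numpy(), alpha)
    res["log2_fc"] = fold_change(exp)
    if invivo_signature is not None:
        matched = match_to_invivo(res, invivo_signature, ppm=ppm, alpha=alpha)
        res = res.merge(
            matched.set_index("feature_mz")[["invivo_mz", "ppm_error", "matched"]],
            left_index=True, right_index=True, how="left",
        )
        res["matched"] = res["matched"].fillna(False)
    return res
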