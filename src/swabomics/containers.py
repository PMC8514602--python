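"""Core in-memory containers shared across the pipeline stages.

Tabular data (species counts, covariates, immune panels, feature values) are
held as :class:`pandas.DataFrame` with sample identifiers in the index; the
small dataclasses here add the spectral/run metadata that a plain frame does
not carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: CSTs dominated by a Lactobacillus species (LDOM); the complement
#: (IV: G. vaginalis, VI: B. breve) is Lactobacillus-depleted (LDEPL).
LDOM_CSTS = frozenset({"I", "II", "III", "V", "VII"})
LDEPL_CSTS = frozenset({"IV", "VI"})
ALL_CSTS = ("I", "II", "III", "IV", "V", "VI", "VII")

#: Expected dominant taxon per CST, used to label clusters.
CST_TEMPLATES = {
    "I": "Lactobacillus crispatus",
    "II": "Lactobacillus gasseri",
    "III": "Lactobacillus iners",
    "IV": "Gardnerella vaginalis",
    "V": "Lactobacillus jensenii",
    "VI": "Bifidobacterium breve",
}

#: The four named Lactobacillus species; dominance by any *other*
#: Lactobacillus sends a sample to CST VII.
NAMED_LACTOBACILLI = frozenset(CST_TEMPLATES[c] for c in ("I", "II", "III", "V"))


def dominance_of(cst: str) -> str:
    """Map a CST label to its Lactobacillus dominance class."""
    if cst in LDOM_CSTS:
        return "LDOM"
    if cst in LDEPL_CSTS:
        return "LDEPL"
    raise ValueError(f"unknown CST label: {cst!r}")


@dataclass
class RawSpectrum:
    """A single profile-mode scan: ascending m/z axis with intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    scan_index: int = 0
    polarity: str = "negative"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class PeakList:
    """Centroided peaks retained by detection for one sample."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class FeatureMatrix:
    """Samples x metabolite-feature intensity table with run metadata.

    ``values`` has sample ids in the index and feature m/z (floats, Da) as
    columns.  ``sample_meta`` is indexed identically and may carry
    ``run_order`` (injection index), ``sample_role`` (study / SR / blank /
    dilution) and ``dilution_factor`` columns; absent columns default to a
    study-only, unordered run.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    polarity: str = "negative"
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.index)
        self.sample_meta = self.sample_meta.reindex(self.values.index)
        if "run_order" not in self.sample_meta:
            self.sample_meta["run_order"] = np.arange(len(self.values))
        if "sample_role" not in self.sample_meta:
            self.sample_meta["sample_role"] = "study"
        if "dilution_factor" not in self.sample_meta:
            self.sample_meta["dilution_factor"] = np.nan
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature matrix contains non-finite values")
        mzs = self.feature_mz
        if len(np.unique(mzs)) != len(mzs):
            raise ValueError("duplicate feature m/z within polarity")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_mz(self) -> np.ndarray:
        return np.asarray([float(c) for c in self.values.columns])

    @property
    def run_order(self) -> pd.Series:
        return self.sample_meta["run_order"]

    @property
    def sample_role(self) -> pd.Series:
        return self.sample_meta["sample_role"]

    def subset_role(self, role: str) -> "FeatureMatrix":
        keep = self.sample_meta["sample_role"] == role
        return FeatureMatrix(
            self.values.loc[keep].copy(),
            self.sample_meta.loc[keep].copy(),
            polarity=self.polarity,
            log_scale=self.log_scale,
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            self.sample_meta.copy(),
            polarity=self.polarity,
            log_scale=self.log_scale,
        )


@dataclass
class CSTAssignment:
    """Per-sample community-state-type calls plus the clustering model report.

    ``assignments`` columns: ``cluster`` (int), ``cst`` (label or
    "unassigned"), ``dominance`` ("LDOM"/"LDEPL" or NA).
    """

    assignments: pd.DataFrame
    chosen_k: int = 0
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    cluster_map: dict[int, dict] = field(default_factory=dict)

    @property
    def cst(self) -> pd.Series:
        return self.assignments["cst"]

    @property
    def dominance(self) -> pd.Series:
        return self.assignments["dominance"]
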