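"""Readers and writers for the pipeline's file boundaries.

Spectra come in as mzML (via pyteomics) or two-column whitespace-delimited
text per scan; tables move as CSV/TSV with explicit headers; reports as
JSON.  Feature-matrix CSVs carry feature m/z in the header printed to nine
decimal places, with a JSON sidecar for run metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mzml as pyteomics_mzml

from swabomics.containers import FeatureMatrix, RawSpectrum


def read_scan_text(path: str | Path, scan_index: int = 0) -> RawSpectrum:
    """Read one scan from two-column (m/z, intensity) whitespace text."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    order = np.argsort(arr[:, 0])
    return RawSpectrum(mz=arr[order, 0], intensity=arr[order, 1], scan_index=scan_index)


def write_scan_text(spectrum: RawSpectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]),
               fmt="%.9f %.6f")


def read_mzml_scans(path: str | Path) -> list[RawSpectrum]:
    """Read all MS1 scans from an mzML file (centroid or profile)."""
    scans = []
    with pyteomics_mzml.MzML(str(path)) as reader:
        for i, spec in enumerate(reader):
            if spec.get("ms level", 1) != 1:
                continue
            mz = np.asarray(spec["m/z array"], dtype=float)
            inten = np.asarray(spec["intensity array"], dtype=float)
            order = np.argsort(mz)
            scans.append(RawSpectrum(mz=mz[order], intensity=inten[order], scan_index=i))
    return scans


def read_sample_scans(sample_dir: str | Path) -> list[RawSpectrum]:
    """Read a sample's scans from a directory of .txt scans or one .mzML."""
    sample_dir = Path(sample_dir)
    mzmls = sorted(sample_dir.glob("*.mzML")) + sorted(sample_dir.glob("*.mzml"))
    if mzmls:
        return read_mzml_scans(mzmls[0])
    txts = sorted(sample_dir.glob("*.txt"))
    if not txts:
        raise FileNotFoundError(f"no scans found in {sample_dir}")
    return [read_scan_text(p, scan_index=i) for i, p in enumerate(txts)]


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write values CSV (header m/z at 9 dp) plus a metadata JSON sidecar."""
    path = Path(path)
    out = matrix.values.copy()
    out.columns = [f"{float(c):.9f}" for c in out.columns]
    out.to_csv(path, index_label="sample_id")
    sidecar = {
        "polarity": matrix.polarity,
        "log_scale": matrix.log_scale,
        "sample_meta": {
            "run_order": matrix.run_order.tolist(),
            "sample_role": matrix.sample_role.tolist(),
            "dilution_factor": [
                None if pd.isna(v) else float(v)
                for v in matrix.sample_meta["dilution_factor"]
            ],
        },
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    values = pd.read_csv(path, index_col="sample_id")
    values.columns = [float(c) for c in values.columns]
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    polarity, log_scale, sample_meta = "negative", False, None
    if meta_path.exists():
        sidecar = json.loads(meta_path.read_text())
        polarity = sidecar.get("polarity", "negative")
        log_scale = sidecar.get("log_scale", False)
        sm = sidecar.get("sample_meta", {})
        sample_meta = pd.DataFrame(
            {
                "run_order": sm.get("run_order"),
                "sample_role": sm.get("sample_role"),
                "dilution_factor": [
                    np.nan if v is None else v for v in sm.get("dilution_factor", [])
                ],
            },
            index=values.index,
        )
    return FeatureMatrix(values=values, sample_meta=sample_meta,
                         polarity=polarity, log_scale=log_scale)


def read_species_counts(path: str | Path) -> pd.DataFrame:
    """Samples x species TSV of integer counts."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.astype(int)


def write_species_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.to_csv(path, index_label="sample_id")


def read_immune(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_immune(immune: pd.DataFrame, path: str | Path) -> None:
    immune.to_csv(path, index_label="sample_id")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
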