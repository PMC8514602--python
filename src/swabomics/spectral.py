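"""Raw-spectrum processing: averaging, peak picking, alignment, binning, QC.

The processing chain mirrors standard ambient-MS practice for swab profiling:
the first 30 scans of a sample are averaged into one spectrum; peaks are
detected as strict local maxima exceeding a signal-to-noise threshold, with
noise estimated by the scaled median absolute deviation (MAD); per-sample
m/z axes are warped onto a common reference by locally weighted regression
on matched landmark peaks; aligned peaks are grouped into reference bins by
strict tolerance-bounded binning; and features are drift-corrected and
QC-filtered using pooled study-reference (SR) injections and an SR dilution
series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from swabomics.containers import FeatureMatrix, PeakList, RawSpectrum

MAD_SCALE = 1.4826  # consistency constant for Gaussian noise


@dataclass
class PeakPickingParams:
    """Tunable parameters of the peak-picking and binning chain.

    Half windows are in points (index units) on the m/z axis; ``tolerance``
    is a relative m/z deviation (0.002 means |dm/z| / (m/z) <= 0.002);
    ``min_frequency`` is the fraction of samples a reference bin must occur
    in to be retained.
    """

    snr_detect: float = 3.0
    half_window_detect: int = 10
    snr_align: float = 2.0
    half_window_align: int = 20
    tolerance: float = 0.002
    tolerance_is_relative: bool = True
    min_frequency: float = 0.01
    align_min_landmark_frequency: float = 0.9

    def __post_init__(self) -> None:
        if min(self.snr_detect, self.snr_align, self.tolerance) <= 0:
            raise ValueError("SNR thresholds and tolerance must be positive")
        if self.half_window_detect <= 0 or self.half_window_align <= 0:
            raise ValueError("half windows must be positive")
        if not (0 < self.min_frequency <= 1):
            raise ValueError("min_frequency must lie in (0, 1]")

    def mz_tolerance(self, mz: float) -> float:
        return self.tolerance * mz if self.tolerance_is_relative else self.tolerance


def average_scans(spectra: list[RawSpectrum], n: int = 30) -> RawSpectrum:
    """Average the first ``n`` scans into a single spectrum.

    Scans on differing m/z axes are resampled (linear interpolation) onto
    the first scan's axis before the pointwise mean.
    """
    if not spectra:
        raise ValueError("no scans supplied")
    used = spectra[: min(n, len(spectra))]
    axis = used[0].mz
    stack = np.empty((len(used), axis.size))
    for i, sc in enumerate(used):
        if sc.mz.shape == axis.shape and np.array_equal(sc.mz, axis):
            stack[i] = sc.intensity
        else:
            stack[i] = np.interp(axis, sc.mz, sc.intensity)
    return RawSpectrum(
        mz=axis.copy(),
        intensity=stack.mean(axis=0),
        scan_index=0,
        polarity=used[0].polarity,
    )


def estimate_noise(spectrum: RawSpectrum) -> float:
    """MAD noise estimate, constant across the spectrum.

    noise = 1.4826 * median(|I - median(I)|); 0 for a constant spectrum.
    """
    if len(spectrum) < 2:
        raise ValueError("need at least two points to estimate noise")
    inten = spectrum.intensity
    return float(MAD_SCALE * np.median(np.abs(inten - np.median(inten))))


def detect_peaks(
    spectrum: RawSpectrum,
    params: PeakPickingParams | None = None,
    sample_id: str = "",
) -> PeakList:
    """Detect peaks as strict local maxima above an SNR threshold.

    A point is a peak iff it is the maximum within +/- ``half_window_detect``
    points, no equal-intensity point precedes it inside the window (ties
    break toward lower m/z), and its SNR reaches ``snr_detect``.  When the
    MAD noise estimate is zero, any positive intensity is treated as
    infinite SNR so that noiseless spectra still yield their maxima; an
    all-zero spectrum yields no peaks.
    """
    params = params or PeakPickingParams()
    inten = spectrum.intensity
    n = inten.size
    noise = estimate_noise(spectrum)
    hw = params.half_window_detect
    idx = []
    for i in range(n):
        if inten[i] <= 0:
            continue
        lo, hi = max(0, i - hw), min(n, i + hw + 1)
        window = inten[lo:hi]
        if inten[i] < window.max():
            continue
        if np.any(inten[lo:i] == inten[i]):
            continue  # tie broken to the lower-m/z point
        idx.append(i)
    idx = np.asarray(idx, dtype=int)
    if noise > 0:
        snr = inten[idx] / noise
    else:
        snr = np.full(idx.size, np.inf)
    keep = snr >= params.snr_detect
    return PeakList(
        mz=spectrum.mz[idx[keep]],
        intensity=inten[idx[keep]],
        snr=snr[keep],
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# alignment


def _strict_bins(mzs: np.ndarray, samples: np.ndarray, tol_rel: float):
    """Recursive strict binning of sorted peak m/z values.

    A group is a bin iff its relative span is <= tol_rel and no sample
    occurs twice; otherwise it is split at the largest adjacent gap.
    Yields index arrays into the sorted input.
    """
    order = np.argsort(mzs, kind="stable")

    def recurse(ix: np.ndarray):
        m = mzs[ix]
        span_ok = (m[-1] - m[0]) <= tol_rel * m.mean()
        unique_ok = len(np.unique(samples[ix])) == len(ix)
        if span_ok and unique_ok:
            yield ix
            return
        if len(ix) == 1:
            yield ix
            return
        gaps = np.diff(m)
        if gaps.max() == 0:
            # identical m/z from the same sample: keep one peak per sample
            for s in np.unique(samples[ix]):
                yield ix[samples[ix] == s][:1]
            return
        cut = int(np.argmax(gaps)) + 1
        yield from recurse(ix[:cut])
        yield from recurse(ix[cut:])

    yield from recurse(order)


def build_reference_peaks(
    peaklists: list[PeakList],
    params: PeakPickingParams,
    min_frequency: float,
) -> np.ndarray:
    """Reference m/z landmarks: strict bins present in >= min_frequency of samples."""
    mzs, samp = [], []
    for i, pl in enumerate(peaklists):
        mzs.append(pl.mz)
        samp.append(np.full(len(pl), i))
    mz_all = np.concatenate(mzs)
    samp_all = np.concatenate(samp)
    if mz_all.size == 0:
        return np.array([])
    n_samples = len(peaklists)
    refs = []
    for ix in _strict_bins(mz_all, samp_all, params.tolerance):
        if len(ix) / n_samples >= min_frequency:
            refs.append(mz_all[ix].mean())
    return np.sort(np.asarray(refs))


def align_peaks(
    peaklists: list[PeakList], params: PeakPickingParams | None = None
) -> list[PeakList]:
    """Warp each sample's m/z axis onto reference landmarks.

    Landmarks are high-frequency strict bins across samples (only peaks with
    SNR >= ``snr_align`` participate).  Each sample's matched
    landmark displacements are smoothed by locally weighted regression
    (linear fit when fewer than four matches) and the fitted shift is
    subtracted from every peak m/z.  A sample with fewer than two landmark
    matches keeps its original axis (identity warp) with a warning.
    """
    params = params or PeakPickingParams()
    if len(peaklists) < 2:
        raise ValueError("alignment requires at least two peak lists")
    strong = [
        PeakList(
            pl.mz[pl.snr >= params.snr_align],
            pl.intensity[pl.snr >= params.snr_align],
            pl.snr[pl.snr >= params.snr_align],
            pl.sample_id,
        )
        for pl in peaklists
    ]
    refs = build_reference_peaks(
        strong, params, params.align_min_landmark_frequency
    )
    out = []
    for pl in peaklists:
        warped = _warp_sample(pl, refs, params)
        out.append(warped)
    return out


def _warp_sample(
    pl: PeakList, refs: np.ndarray, params: PeakPickingParams
) -> PeakList:
    if len(pl) == 0 or refs.size == 0:
        return PeakList(pl.mz.copy(), pl.intensity.copy(), pl.snr.copy(), pl.sample_id)
    # match each peak to its nearest reference within tolerance
    pos = np.searchsorted(refs, pl.mz)
    cand = np.clip(np.stack([pos - 1, pos]), 0, refs.size - 1)
    dists = np.abs(refs[cand] - pl.mz[None, :])
    nearest = cand[np.argmin(dists, axis=0), np.arange(len(pl))]
    err = pl.mz - refs[nearest]
    tol = np.array([params.mz_tolerance(m) for m in pl.mz])
    matched = np.abs(err) <= tol
    if matched.sum() < 2:
        warnings.warn(
            f"sample {pl.sample_id!r}: fewer than two landmark matches; "
            "identity warp applied",
            stacklevel=2,
        )
        return PeakList(pl.mz.copy(), pl.intensity.copy(), pl.snr.copy(), pl.sample_id)
    x = pl.mz[matched]
    shift = err[matched]
    if matched.sum() < 4:
        coef = np.polyfit(x, shift, deg=1)
        fitted_shift = np.polyval(coef, pl.mz)
    else:
        sm = lowess(shift, x, frac=2 / 3, return_sorted=True)
        fitted_shift = np.interp(pl.mz, sm[:, 0], sm[:, 1])
    new_mz = pl.mz - fitted_shift
    order = np.argsort(new_mz, kind="stable")
    return PeakList(
        new_mz[order], pl.intensity[order], pl.snr[order], pl.sample_id
    )


def bin_to_reference(
    peaklists: list[PeakList], params: PeakPickingParams | None = None
) -> FeatureMatrix:
    """Group aligned peaks into reference bins and build the feature matrix.

    Bins are strict (member span <= tolerance, one peak per sample) and must
    occur in >= ``min_frequency`` of samples.  Missing entries are 0; the
    feature m/z is the mean of member m/z.
    """
    params = params or PeakPickingParams()
    sample_ids = [pl.sample_id or str(i) for i, pl in enumerate(peaklists)]
    mzs, samp, inten = [], [], []
    for i, pl in enumerate(peaklists):
        mzs.append(pl.mz)
        samp.append(np.full(len(pl), i))
        inten.append(pl.intensity)
    mz_all = np.concatenate(mzs) if mzs else np.array([])
    samp_all = np.concatenate(samp) if samp else np.array([], dtype=int)
    int_all = np.concatenate(inten) if inten else np.array([])
    n_samples = len(peaklists)
    cols: dict[float, np.ndarray] = {}
    if mz_all.size:
        for ix in _strict_bins(mz_all, samp_all, params.tolerance):
            if len(ix) / n_samples < params.min_frequency:
                continue
            col = np.zeros(n_samples)
            col[samp_all[ix]] = int_all[ix]
            mz_feat = float(mz_all[ix].mean())
            while mz_feat in cols:  # guard against exact collisions
                mz_feat = np.nextafter(mz_feat, np.inf)
            cols[mz_feat] = col
    values = pd.DataFrame(
        {mz: cols[mz] for mz in sorted(cols)}, index=pd.Index(sample_ids, name="sample_id")
    )
    return FeatureMatrix(values=values)


# ---------------------------------------------------------------------------
# drift correction and QC filtering


def correct_drift(
    matrix: FeatureMatrix, frac: float | None = None, anchor: str = "sr_median"
) -> tuple[FeatureMatrix, list[float]]:
    """Divide out a smooth per-feature intensity drift fitted on SR samples.

    Per feature, a locally weighted trend of SR intensity versus injection
    index is fitted (span ``frac``, default covering two thirds of the SR
    points), interpolated to every sample's index, and divided out.  The
    result is rescaled per feature: with ``anchor='sr_median'`` (default)
    the SR median is unchanged by the correction; with ``anchor='run_start'``
    the trend is normalised to its value at the first injection, restoring
    the instrument response at the start of the run (useful when the run is
    known to open undrifted).  Features whose SR values are all zero are
    left uncorrected and reported back.
    """
    sr_mask = matrix.sample_role == "SR"
    if sr_mask.sum() < 4:
        raise ValueError("drift correction needs at least four SR samples")
    run = matrix.run_order.to_numpy(dtype=float)
    sr_run = run[sr_mask.to_numpy()]
    vals = matrix.values.to_numpy(dtype=float).copy()
    sr_vals = vals[sr_mask.to_numpy()]
    frac = frac if frac is not None else min(1.0, 2 / 3)
    skipped: list[float] = []
    mz = matrix.feature_mz
    for j in range(vals.shape[1]):
        y = sr_vals[:, j]
        if np.all(y == 0):
            skipped.append(float(mz[j]))
            continue
        sm = lowess(y, sr_run, frac=frac, return_sorted=True)
        trend = np.interp(run, sm[:, 0], sm[:, 1])
        trend = np.where(trend <= 0, np.nan, trend)  # non-positive trend: leave value as-is
        with np.errstate(invalid="ignore"):
            corrected = vals[:, j] / trend
        if anchor == "run_start":
            scale = float(np.interp(run.min(), sm[:, 0], sm[:, 1]))
        elif anchor == "sr_median":
            sr_corr = corrected[sr_mask.to_numpy()]
            scale = np.nanmedian(y) / np.nanmedian(sr_corr) if np.nanmedian(sr_corr) else 1.0
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        corrected = corrected * scale
        corrected = np.where(np.isnan(corrected), vals[:, j], corrected)
        vals[:, j] = corrected
    out = matrix.copy()
    out.values.loc[:, :] = vals
    if skipped:
        warnings.warn(
            f"{len(skipped)} feature(s) with all-zero SR values left uncorrected",
            stacklevel=2,
        )
    return out, skipped


def filter_features_qc(
    matrix: FeatureMatrix,
    max_sr_cv: float = 0.30,
    min_dilution_r: float = 0.7,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """QC filter: keep features reproducible in SR and linear in dilution.

    A feature passes iff its coefficient of variation across repeated SR
    injections is <= ``max_sr_cv`` and its Pearson correlation with the SR
    dilution factor is >= ``min_dilution_r``.  Returns the matrix restricted
    to study samples and passing features, plus a per-feature QC report.
    """
    roles = matrix.sample_role
    sr = matrix.values.loc[roles == "SR"]
    if sr.empty:
        raise ValueError("QC filtering requires SR samples")
    dil = matrix.values.loc[roles == "dilution"]
    dil_factor = matrix.sample_meta.loc[roles == "dilution", "dilution_factor"]
    means = sr.mean(axis=0)
    sds = sr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sds / means).replace([np.inf, -np.inf], np.nan)
    report = pd.DataFrame({"sr_cv": cv})
    if dil.empty:
        warnings.warn("no dilution series present; dilution filter skipped", stacklevel=2)
        report["dilution_r"] = np.nan
        pass_dil = pd.Series(True, index=matrix.values.columns)
    else:
        x = dil_factor.to_numpy(dtype=float)
        xc = x - x.mean()
        y = dil.to_numpy(dtype=float)
        yc = y - y.mean(axis=0)
        denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, (xc @ yc) / denom, np.nan)
        report["dilution_r"] = r
        pass_dil = pd.Series(report["dilution_r"] >= min_dilution_r, index=matrix.values.columns)
    pass_cv = cv.fillna(np.inf) <= max_sr_cv
    report["pass_cv"] = pass_cv
    report["pass_dilution"] = pass_dil
    report["retained"] = pass_cv & pass_dil
    keep_cols = report.index[report["retained"]]
    study = roles == "study"
    filtered = FeatureMatrix(
        matrix.values.loc[study, keep_cols].copy(),
        matrix.sample_meta.loc[study].copy(),
        polarity=matrix.polarity,
        log_scale=matrix.log_scale,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# end-to-end convenience


def process_spectra(
    scans_by_sample: dict[str, list[RawSpectrum]],
    params: PeakPickingParams | None = None,
    n_scans: int = 30,
) -> FeatureMatrix:
    """Raw scans to a binned feature matrix: average, detect, align, bin."""
    params = params or PeakPickingParams()
    peaklists = []
    for sid, scans in scans_by_sample.items():
        avg = average_scans(scans, n=n_scans)
        peaklists.append(detect_peaks(avg, params, sample_id=sid))
    aligned = align_peaks(peaklists, params)
    return bin_to_reference(aligned, params)
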