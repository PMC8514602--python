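"""Spectral processing: averaging, MAD noise, peak picking, alignment,
strict binning, drift correction and QC filtering."""

import numpy as np
import pandas as pd
import pytest

from swabomics.containers import FeatureMatrix, PeakList, RawSpectrum
from swabomics.spectral import (
    PeakPickingParams,
    align_peaks,
    average_scans,
    bin_to_reference,
    correct_drift,
    detect_peaks,
    estimate_noise,
    filter_features_qc,
    process_spectra,
)
from swabomics.synthetic import add_reference_samples, inject_drift


def _gauss_spectrum(apex=100.0, centre=500.0, noise_amp=0.0, rng=None):
    mz = np.arange(490.0, 510.0, 0.01)
    inten = apex * np.exp(-0.5 * ((mz - centre) / 0.02) ** 2)
    if noise_amp and rng is not None:
        inten = inten + rng.uniform(0, noise_amp, mz.size)
    return RawSpectrum(mz=mz, intensity=inten)


class TestAverageScans:
    def test_mean_of_identical_scans(self):
        sc = _gauss_spectrum()
        out = average_scans([sc] * 30)
        np.testing.assert_allclose(out.intensity, sc.intensity)

    def test_pointwise_mean(self):
        mz = np.array([1.0, 2.0])
        a = RawSpectrum(mz=mz, intensity=np.array([0.0, 0.0]))
        b = RawSpectrum(mz=mz, intensity=np.array([10.0, 4.0]))
        out = average_scans([a, b])
        np.testing.assert_allclose(out.intensity, [5.0, 2.0])

    def test_scans_beyond_n_ignored(self):
        mz = np.array([1.0, 2.0])
        scans = [RawSpectrum(mz=mz, intensity=np.array([1.0, 1.0]))] * 40
        base = average_scans(scans, n=30)
        perturbed = scans[:30] + [
            RawSpectrum(mz=mz, intensity=np.array([99.0, 99.0]))
        ] * 10
        out = average_scans(perturbed, n=30)
        np.testing.assert_array_equal(base.intensity, out.intensity)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            average_scans([])


class TestNoise:
    def test_constant_spectrum(self):
        sp = RawSpectrum(mz=np.arange(5.0), intensity=np.full(5, 7.0))
        assert estimate_noise(sp) == 0.0

    def test_hand_computed_mad(self):
        sp = RawSpectrum(mz=np.arange(1.0, 10.0), intensity=np.arange(1.0, 10.0))
        # median 5, |dev| median 2, scaled by 1.4826
        assert estimate_noise(sp) == pytest.approx(2.9652, abs=1e-4)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        inten = rng.uniform(0, 10, 50)
        sp1 = RawSpectrum(mz=np.arange(50.0), intensity=inten)
        sp2 = RawSpectrum(mz=np.arange(50.0), intensity=inten + 100)
        assert estimate_noise(sp1) == pytest.approx(estimate_noise(sp2))


class TestDetectPeaks:
    def test_single_gaussian_on_noise(self):
        rng = np.random.default_rng(1)
        sp = _gauss_spectrum(apex=100.0, noise_amp=3.0, rng=rng)
        peaks = detect_peaks(sp, PeakPickingParams())
        assert len(peaks) == 1
        assert peaks.mz[0] == pytest.approx(500.0, abs=0.02)

    def test_subthreshold_apex_rejected(self):
        rng = np.random.default_rng(2)
        noise = rng.uniform(0, 2.4, 2000)  # MAD-scale ~ 1
        sp = RawSpectrum(mz=np.arange(2000.0), intensity=noise)
        apex_added = noise.copy()
        apex_added[1000] = 2.0  # SNR ~ 2 < 3
        sp2 = RawSpectrum(mz=np.arange(2000.0), intensity=apex_added)
        p1 = detect_peaks(sp2, PeakPickingParams(snr_detect=3.0))
        assert 1000 not in [int(m) for m in p1.mz]
        _ = sp  # noise-only fixture documents the scale

    def test_tie_breaks_to_lower_mz(self):
        inten = np.zeros(50)
        inten[20] = 10.0
        inten[25] = 10.0  # within one half-window of index 20
        sp = RawSpectrum(mz=np.arange(50.0), intensity=inten)
        peaks = detect_peaks(sp, PeakPickingParams(half_window_detect=10))
        assert list(peaks.mz) == [20.0]


class TestAlignment:
    def _peaklists(self, shift_ppm=0.0, n=6):
        base = np.array([200.0, 400.0, 600.0, 800.0])
        out = []
        for i in range(n):
            factor = 1 + (shift_ppm * 1e-6 if i == n - 1 else 0.0)
            out.append(
                PeakList(mz=base * factor, intensity=np.full(4, 100.0),
                         snr=np.full(4, 50.0), sample_id=f"s{i}")
            )
        return out

    def test_identity_when_already_aligned(self):
        pls = self._peaklists()
        aligned = align_peaks(pls, PeakPickingParams())
        for before, after in zip(pls, aligned):
            np.testing.assert_allclose(after.mz, before.mz, atol=1e-9)

    def test_shifted_sample_improves(self):
        pls = self._peaklists(shift_ppm=500.0)  # +0.05%
        ref = np.array([200.0, 400.0, 600.0, 800.0])
        aligned = align_peaks(pls, PeakPickingParams())
        before = np.abs(pls[-1].mz - ref) / ref * 1e6
        after = np.abs(aligned[-1].mz - ref) / ref * 1e6
        assert np.median(after) < np.median(before)

    def test_peak_count_preserved(self):
        pls = self._peaklists(shift_ppm=300.0)
        aligned = align_peaks(pls, PeakPickingParams())
        assert [len(a) for a in aligned] == [len(p) for p in pls]

    def test_unmatchable_sample_identity_warp(self):
        pls = self._peaklists(n=20)
        lonely = PeakList(mz=np.array([55.0, 65.0]), intensity=np.full(2, 10.0),
                          snr=np.full(2, 50.0), sample_id="odd")
        with pytest.warns(UserWarning, match="identity warp"):
            aligned = align_peaks(pls + [lonely], PeakPickingParams())
        np.testing.assert_array_equal(aligned[-1].mz, lonely.mz)


class TestBinning:
    def _single_peak_lists(self, mz_values):
        return [
            PeakList(mz=np.array([m]), intensity=np.array([10.0]),
                     snr=np.array([50.0]), sample_id=f"s{i}")
            for i, m in enumerate(mz_values)
        ]

    def test_close_peaks_one_bin(self):
        # 0.5/500 = 0.001 <= 0.002 relative tolerance
        fm = bin_to_reference(self._single_peak_lists([500.0, 500.5]),
                              PeakPickingParams(min_frequency=0.01))
        assert fm.values.shape[1] == 1

    def test_distant_peaks_two_bins(self):
        # 2/500 = 0.004 > 0.002
        fm = bin_to_reference(self._single_peak_lists([500.0, 502.0]),
                              PeakPickingParams(min_frequency=0.01))
        assert fm.values.shape[1] == 2

    def test_rare_feature_dropped(self):
        lists = self._single_peak_lists([500.0] * 199)
        lists.append(
            PeakList(mz=np.array([800.0]), intensity=np.array([5.0]),
                     snr=np.array([50.0]), sample_id="s199")
        )
        fm = bin_to_reference(lists, PeakPickingParams(min_frequency=0.01))
        # 1/200 = 0.005 < 0.01: the 800 Da bin is dropped
        assert fm.values.shape[1] == 1
        assert fm.feature_mz[0] == pytest.approx(500.0)

    def test_sample_order_invariance(self, tiny_spectra_cohort):
        spectra = tiny_spectra_cohort.spectra
        params = PeakPickingParams()
        fm1 = process_spectra(spectra, params, n_scans=3)
        reversed_spectra = dict(reversed(list(spectra.items())))
        fm2 = process_spectra(reversed_spectra, params, n_scans=3)
        common = fm1.values.index
        np.testing.assert_allclose(
            fm1.values.loc[common].to_numpy(),
            fm2.values.loc[common, fm1.values.columns].to_numpy(),
            rtol=1e-9,
        )


class TestEndToEnd:
    def test_zero_noise_round_trip(self, tiny_spectra_cohort):
        cohort = tiny_spectra_cohort
        fm = process_spectra(cohort.spectra, PeakPickingParams(), n_scans=3)
        true_mz = cohort.config.feature_mz
        found_mz = fm.feature_mz
        assert len(found_mz) == len(true_mz)  # precision = recall = 1
        for t in true_mz:
            err = np.min(np.abs(found_mz - t)) / t
            assert err <= 0.002
        # monotone recovery: rank correlation with generating intensities
        gen = np.exp(cohort.metabolome.values.to_numpy())
        rec = fm.values.loc[cohort.metabolome.sample_ids].to_numpy()
        from scipy.stats import spearmanr
        for j in range(gen.shape[1]):
            assert spearmanr(gen[:, j], rec[:, j]).statistic > 0.95

    def test_intensity_doubling_doubles_apex(self, tiny_spectra_cohort):
        from swabomics.synthetic import synthesize_spectra
        cfg = tiny_spectra_cohort.config
        rng = np.random.default_rng(0)
        base = np.full(cfg.n_features, 50.0)
        s1 = synthesize_spectra(base, cfg, rng)[0]
        s2 = synthesize_spectra(2 * base, cfg, np.random.default_rng(0))[0]
        assert s2.intensity.max() == pytest.approx(2 * s1.intensity.max())


class TestDriftAndQC:
    def _run_matrix(self, n_samples=12, n_features=4, seed=0):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(
            rng.uniform(50, 150, size=(n_samples, n_features)),
            index=[f"s{i}" for i in range(n_samples)],
            columns=np.linspace(100.0, 400.0, n_features),
        )
        return add_reference_samples(FeatureMatrix(values=vals), sr_spacing=3)

    def test_no_drift_identity(self):
        run = self._run_matrix()
        corrected, skipped = correct_drift(run)
        np.testing.assert_allclose(
            corrected.values.to_numpy(), run.values.to_numpy(), rtol=1e-9
        )
        assert skipped == []

    def test_ramp_round_trip_sr_cv(self):
        run = self._run_matrix()
        drifted, _ = inject_drift(run, 0.5)
        corrected, _ = correct_drift(drifted)
        sr = corrected.values.loc[corrected.sample_role == "SR"]
        cv = (sr.std(ddof=1) / sr.mean()).max()
        assert cv < 0.01

    def test_run_start_anchor_recovers_predrift(self):
        run = self._run_matrix()
        drifted, _ = inject_drift(run, 0.5)
        corrected, _ = correct_drift(drifted, anchor="run_start")
        study = run.sample_role == "study"
        rel = (corrected.values.loc[study] - run.values.loc[study]).abs() \
            / run.values.loc[study]
        assert rel.to_numpy().max() < 0.05

    def test_sign_never_changes(self):
        run = self._run_matrix()
        drifted, _ = inject_drift(run, 0.3)
        corrected, _ = correct_drift(drifted)
        assert (corrected.values.to_numpy() >= 0).all()

    def test_qc_cv_rule(self):
        run = self._run_matrix(seed=3)
        vals = run.values.copy()
        sr_rows = run.sample_role == "SR"
        # make feature 0 wildly irreproducible in SR: CV 50%
        sr_idx = vals.index[sr_rows]
        vals.loc[sr_idx, vals.columns[0]] = np.linspace(
            50, 150, sr_rows.sum()
        )
        noisy = FeatureMatrix(vals, run.sample_meta.copy())
        filtered, report = filter_features_qc(noisy)
        assert not report["pass_cv"].iloc[0]
        assert report["pass_cv"].iloc[1:].all()

    def test_qc_dilution_rule(self):
        run = self._run_matrix(seed=4)
        vals = run.values.copy()
        dil_rows = run.sample_role == "dilution"
        # feature 0 anti-correlated with dilution factor
        factors = run.sample_meta.loc[dil_rows, "dilution_factor"]
        vals.loc[factors.index, vals.columns[0]] = 100.0 - 50.0 * factors
        broken = FeatureMatrix(vals, run.sample_meta.copy())
        filtered, report = filter_features_qc(broken)
        assert not report["pass_dilution"].iloc[0]
        assert float(report["dilution_r"].iloc[1]) > 0.99
        assert str(filtered.values.columns[0]) != str(vals.columns[0])

    def test_missing_dilution_warns(self):
        run = self._run_matrix()
        keep = run.sample_role != "dilution"
        trimmed = FeatureMatrix(
            run.values.loc[keep].copy(), run.sample_meta.loc[keep].copy()
        )
        with pytest.warns(UserWarning, match="dilution"):
            _, report = filter_features_qc(trimmed)
        assert report["dilution_r"].isna().all()
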