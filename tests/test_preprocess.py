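"""Background estimation, recalibration, extraction, QC, normalization."""

import numpy as np
import pandas as pd
import pytest

from glycotof.chem import elemental_formula, isotope_envelope
from glycotof.features import GlycanFeature, FeatureList, enumerate_default_features
from glycotof.io import Spectrum
from glycotof.preprocess import (
    AnalyteExtraction,
    GlycomeProfile,
    PreprocessError,
    estimate_background,
    extract_all,
    extract_feature,
    known_peak_positions,
    normalize_profile,
    process_spectrum,
    qc_spectrum,
    recalibrate,
)
from glycotof.synthetic import (
    DEFAULT_CALIBRANTS,
    SpectrumRenderConfig,
    baseline_profile,
    render_spectrum,
)


def flat_spectrum(level=5.0, lo=1000.0, hi=1100.0, step=0.02):
    mz = np.arange(lo, hi, step)
    return Spectrum(mz, np.full(mz.size, level))


class TestBackground:
    def test_flat_no_peaks(self):
        bg, noise = estimate_background(flat_spectrum(level=7.5), 1050.0, flank=10.0)
        assert bg == pytest.approx(7.5, abs=1e-12)
        assert noise == pytest.approx(0.0, abs=1e-12)

    def test_noisy_flat_recovers_level_and_sigma(self, rng):
        mz = np.arange(1000, 1040, 0.004)  # 5000 points in the window
        spec = Spectrum(mz, np.clip(100.0 + rng.normal(0, 5.0, mz.size), 0, None))
        bg, noise = estimate_background(spec, 1020.0, flank=10.0)
        assert bg == pytest.approx(100.0, rel=0.10)
        assert noise == pytest.approx(5.0, rel=0.10)

    def test_huge_peak_does_not_bias(self):
        spec = flat_spectrum(level=3.0)
        inten = spec.intensity.copy()
        center = 1050.0
        inten += 1e5 * np.exp(-0.5 * ((spec.mz - center) / 0.06) ** 2)
        spec = Spectrum(spec.mz, inten)
        bg, _ = estimate_background(spec, center, flank=10.0, exclude_mz=np.array([center]))
        assert bg == pytest.approx(3.0, abs=0.01)

    def test_empty_window_rejected(self):
        with pytest.raises(PreprocessError, match="empty"):
            estimate_background(flat_spectrum(), 5000.0, flank=1.0)
        with pytest.raises(PreprocessError):
            estimate_background(flat_spectrum(), 1050.0, flank=-1.0)


def render_baseline(noise=0.0, distortion=(0.0, 0.0, 0.0), seed=1, **kw):
    fl = enumerate_default_features()
    cfg = SpectrumRenderConfig(noise_sigma=noise, distortion_ppm=distortion, **kw)
    rng = np.random.default_rng(seed) if noise > 0 else None
    prof = GlycomeProfile(baseline_profile("plasma"))
    return fl, cfg, render_spectrum(prof, fl, cfg, rng), prof


class TestRecalibration:
    def test_recovers_injected_quadratic_distortion(self):
        fl, cfg, spec, _ = render_baseline(noise=2.0, distortion=(20.0, 15.0, 10.0))
        exclude = known_peak_positions(fl, cfg.calibrants)
        cal_spec, result = recalibrate(spec, cfg.calibrants, exclude_mz=exclude)
        assert result.passed
        assert result.n_found == len(cfg.calibrants)
        assert result.max_residual_ppm < 5.0

    def test_identity_on_grid_aligned_calibrants(self):
        # calibrant-only spectrum with peaks exactly on grid points:
        # the fit must recover the identity mapping
        mz = np.arange(1000.0, 3000.0, 0.02)
        inten = np.full(mz.size, 1.0)
        cals = [1100.0, 1400.0, 1700.0, 2000.0, 2300.0, 2600.0]
        for c in cals:
            inten += 5000.0 * np.exp(-0.5 * ((mz - c) / 0.0637) ** 2)
        spec = Spectrum(mz, inten)
        cal_spec, result = recalibrate(spec, cals)
        assert result.passed
        assert np.max(np.abs(cal_spec.mz - spec.mz)) < 1e-6

    def test_idempotent_within_one_ppm(self):
        fl, cfg, spec, _ = render_baseline(noise=2.0, distortion=(20.0, 15.0, 10.0), seed=3)
        exclude = known_peak_positions(fl, cfg.calibrants)
        once, r1 = recalibrate(spec, cfg.calibrants, exclude_mz=exclude)
        twice, r2 = recalibrate(once, cfg.calibrants, exclude_mz=exclude)
        assert abs(r2.max_residual_ppm - r1.max_residual_ppm) < 1.0

    def test_too_few_detectable_calibrants_excludes(self):
        fl, cfg, spec, _ = render_baseline(noise=2.0)
        # only 4 of these 6 masses carry rendered calibrant peaks
        cals = list(cfg.calibrants[:4]) + [1500.0, 1800.0]
        _, result = recalibrate(spec, cals, exclude_mz=known_peak_positions(fl, cals))
        assert not result.passed
        assert "only 4" in result.reason

    def test_fewer_calibrants_than_required_is_config_error(self):
        spec = flat_spectrum()
        with pytest.raises(PreprocessError, match="calibrant"):
            recalibrate(spec, [1050.0, 1060.0], min_found=5)


class TestExtraction:
    def test_noiseless_envelope_recovered_within_one_percent(self, feature_list):
        f = feature_list["H5N4Ge2"]
        cfg = SpectrumRenderConfig(noise_sigma=0.0, baseline_level=10.0, baseline_slope=0.0)
        prof = pd.Series(0.0, index=feature_list.names)
        prof["H5N4Ge2"] = 100.0
        spec = render_spectrum(prof, feature_list, cfg)
        ext = extract_feature(spec, f)
        # total envelope area is abundance * intensity_scale
        assert ext.area == pytest.approx(100.0 * cfg.intensity_scale, rel=0.01)
        assert ext.qc_pass

    def test_no_peak_gives_zero_area(self, feature_list):
        spec = flat_spectrum(level=4.0, lo=2300, hi=2400)
        f = feature_list["H5N4Ge2"]
        ext = extract_feature(spec, f)
        assert ext.area == pytest.approx(0.0, abs=1e-9)
        assert not ext.qc_pass

    def test_out_of_range_flagged(self, feature_list):
        spec = flat_spectrum(lo=1000, hi=1100)
        ext = extract_feature(spec, feature_list["H5N4Ge2"])
        assert ext.out_of_range
        assert ext.area == 0.0

    def test_overlapping_targets_warn(self, feature_list):
        a = feature_list["H5N4Ge2"]
        shifted = GlycanFeature(
            feature_list["H5N4Ge1Gl1"].composition, a.mz + 0.3, "complex", 2, 2
        )
        fl = FeatureList([a, shifted])
        spec = flat_spectrum(lo=2300, hi=2400)
        with pytest.warns(UserWarning, match="integration windows"):
            extract_all(spec, fl)


class TestQC:
    def _ext(self, feature, area, snr):
        return AnalyteExtraction(feature, area, np.array([area]), 0.0, 1.0, snr, snr > 9)

    def test_all_good(self, feature_list):
        exts = [self._ext(f, 10.0, 50.0) for f in list(feature_list)[:4]]
        qc = qc_spectrum(exts)
        assert qc.passed and qc.fraction == 1.0

    def test_boundary_forty_five_percent_inclusive(self, feature_list):
        f1, f2 = list(feature_list)[:2]
        exts = [self._ext(f1, 45.0, 50.0), self._ext(f2, 55.0, 1.0)]
        assert qc_spectrum(exts).passed

    def test_below_threshold_fails(self, feature_list):
        f1, f2 = list(feature_list)[:2]
        exts = [self._ext(f1, 30.0, 50.0), self._ext(f2, 70.0, 1.0)]
        qc = qc_spectrum(exts)
        assert not qc.passed
        assert qc.fraction == pytest.approx(0.30)

    def test_zero_total_area_fails_with_reason(self, feature_list):
        exts = [self._ext(list(feature_list)[0], 0.0, 0.0)]
        qc = qc_spectrum(exts)
        assert not qc.passed and "zero" in qc.reason


class TestNormalization:
    def test_equal_areas(self, feature_list):
        exts = [
            AnalyteExtraction(f, 5.0, np.array([5.0]), 0, 1, 50, True)
            for f in list(feature_list)[:4]
        ]
        prof = normalize_profile(exts)
        assert (prof.abundances == 25.0).all()

    def test_single_nonzero(self, feature_list):
        f1, f2 = list(feature_list)[:2]
        exts = [
            AnalyteExtraction(f1, 3.0, np.array([3.0]), 0, 1, 50, True),
            AnalyteExtraction(f2, 0.0, np.array([0.0]), 0, 1, 0, False),
        ]
        prof = normalize_profile(exts)
        assert prof.abundances[f1.name] == 100.0

    def test_zero_total_rejected(self, feature_list):
        exts = [AnalyteExtraction(list(feature_list)[0], 0.0, np.array([0.0]), 0, 1, 0, False)]
        with pytest.raises(PreprocessError):
            normalize_profile(exts)


class TestPipelineInvariants:
    def test_scale_invariance(self, feature_list):
        _, cfg, spec, prof = render_baseline(noise=2.0, seed=9)
        p1, _ = process_spectrum(spec, feature_list, list(cfg.calibrants))
        scaled = Spectrum(spec.mz, spec.intensity * 7.3, spec.sample_id)
        p2, _ = process_spectrum(scaled, feature_list, list(cfg.calibrants))
        pd.testing.assert_series_equal(p1.abundances, p2.abundances, rtol=1e-9)

    def test_noiseless_profile_recovery(self, feature_list):
        _, cfg, spec, prof = render_baseline(noise=0.0)
        rec, report = process_spectrum(spec, feature_list, list(cfg.calibrants))
        assert report.included
        err = rec.abundances - prof.abundances.reindex(rec.abundances.index).fillna(0.0)
        assert err.abs().max() < 0.1

    def test_qc_fraction_decreases_with_noise(self, feature_list):
        # baseline high enough that additive noise is never clipped at zero
        fractions = []
        for sigma in (2.0, 30.0, 90.0):
            fl, cfg, spec, _ = render_baseline(
                noise=sigma, seed=5, calibrant_area=3000.0,
                baseline_level=400.0, baseline_slope=0.0,
            )
            _, report = process_spectrum(spec, feature_list, list(cfg.calibrants))
            fractions.append(report.qc.fraction)
        assert fractions[0] > fractions[1] > fractions[2]
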