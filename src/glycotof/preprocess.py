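"""Targeted spectrum processing: recalibration, extraction, QC, normalization.

The stage mirrors the standard targeted MALDI-TOF glycomics workflow:

1. the m/z axis is recalibrated against a list of calibrant masses
   (quadratic least squares on calibrant apexes; a spectrum is usable
   only if at least five calibrants are found at S/N >= 9),
2. for each feature of the target list the isotopic envelope is
   integrated after dynamic local background subtraction,
3. spectra in which less than 45 % of the total analyte area comes from
   features above S/N 9 are excluded,
4. surviving spectra are normalized to total area 100 %.

Background is estimated per isotopic peak as the mean of the lowest 20 %
of intensities in a +-``flank`` Da window (excluding +-0.35 Da around
known peaks), and noise as the RMS deviation of those background points
about that level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import elemental_formula, isotope_envelope
from .features import FeatureList, GlycanFeature
from .io import Spectrum

__all__ = [
    "CalibrantFit",
    "CalibrationResult",
    "AnalyteExtraction",
    "QCResult",
    "GlycomeProfile",
    "estimate_background",
    "recalibrate",
    "extract_feature",
    "extract_all",
    "qc_spectrum",
    "normalize_profile",
    "process_spectrum",
    "known_peak_positions",
    "PreprocessError",
]

PEAK_EXCLUSION_HALFWIDTH = 0.35  # Da masked around known peaks in background windows
DEFAULT_FLANK = 10.0  # Da, half-width of the dynamic background window
DEFAULT_TOL = 0.25  # Da, integration half-window per isotopologue
DEFAULT_COVERAGE = 0.95  # isotopic-envelope coverage used for extraction
SNR_MIN = 9.0
QC_MIN_FRACTION = 0.45
CALIBRANT_SEARCH_TOL = 0.3  # Da, apex search window around each calibrant


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# background / noise
# ---------------------------------------------------------------------------

# Lowest-quintile order statistics of a Gaussian: with z = Phi^-1(0.2),
# lam = phi(z)/0.2, the quintile mean is mu - lam*sigma and its SD about
# that mean is sigma*sqrt(1 - z*lam - lam^2).
_QUINTILE_SHIFT = 1.3998096  # lam
_QUINTILE_SD = 0.4675881  # sqrt(1 - z*lam - lam^2)

def estimate_background(
    spec: Spectrum,
    window_center: float,
    flank: float = DEFAULT_FLANK,
    exclude_mz: np.ndarray | None = None,
    exclude_halfwidth: float = PEAK_EXCLUSION_HALFWIDTH,
) -> tuple[float, float]:
    """Dynamic local background and RMS noise around ``window_center``.

    Points within ``exclude_halfwidth`` of any position in ``exclude_mz``
    (known feature isotopologues and calibrants) are masked out and the
    lowest 20 % of the remaining intensities are taken as background
    points — robust against unlisted peaks, which only ever push points
    *up*.  Because the lowest quintile of a noisy baseline sits below its
    true level, the mean and RMS of those points are corrected with the
    Gaussian truncated-distribution factors, so that on a flat baseline
    ``b`` with noise ``sigma`` the estimates converge to ``(b, sigma)``.
    """
    if flank <= 0:
        raise PreprocessError("flank must be positive")
    mz, inten = spec.slice(window_center - flank, window_center + flank)
    if mz.size == 0:
        raise PreprocessError(
            f"empty background window around m/z {window_center:.2f} (+-{flank} Da)"
        )
    if exclude_mz is not None and len(exclude_mz) > 0:
        ex = np.asarray(exclude_mz, dtype=float)
        ex = ex[(ex >= mz[0] - exclude_halfwidth) & (ex <= mz[-1] + exclude_halfwidth)]
        if ex.size:
            # distance from each point to the nearest excluded center
            idx = np.searchsorted(ex, mz)
            left = ex[np.clip(idx - 1, 0, ex.size - 1)]
            right = ex[np.clip(idx, 0, ex.size - 1)]
            dist = np.minimum(np.abs(mz - left), np.abs(mz - right))
            keep = dist > exclude_halfwidth
            if keep.any():
                inten = inten[keep]
    n_low = max(1, int(np.ceil(0.2 * inten.size)))
    low = np.partition(inten, n_low - 1)[:n_low]
    m_low = float(np.mean(low))
    s_low = float(np.std(low))
    # Gaussian lowest-quintile corrections: E[mean] = mu - 1.39981*sigma,
    # E[SD about the quintile mean] = 0.46759*sigma.
    noise = s_low / _QUINTILE_SD
    background = m_low + _QUINTILE_SHIFT * noise
    return background, noise


def known_peak_positions(
    features: FeatureList,
    calibrants: np.ndarray | list[float] | None = None,
    coverage: float = 0.999,
) -> np.ndarray:
    """Sorted m/z of every isotopologue of every feature plus calibrants.

    Used to mask analyte signal out of background windows.
    """
    positions: list[float] = []
    for f in features:
        offsets, _, _ = isotope_envelope(elemental_formula(f.composition), coverage)
        positions.extend(f.mz + o for o in offsets)
    if calibrants is not None:
        positions.extend(float(c) for c in calibrants)
    return np.sort(np.asarray(positions))


# ---------------------------------------------------------------------------
# recalibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrantFit:
    mass: float  # theoretical calibrant m/z
    found: bool
    observed: float | None  # apex m/z before recalibration
    snr: float
    residual_ppm_before: float | None
    residual_ppm_after: float | None


@dataclass
class CalibrationResult:
    coefficients: np.ndarray  # polynomial (highest degree first) observed -> calibrated
    calibrants: list[CalibrantFit]
    passed: bool
    reason: str = ""

    @property
    def n_found(self) -> int:
        return sum(c.found for c in self.calibrants)

    @property
    def max_residual_ppm(self) -> float:
        res = [abs(c.residual_ppm_after) for c in self.calibrants if c.found]
        return max(res) if res else float("nan")


def _apex(spec: Spectrum, center: float, tol: float) -> tuple[float, float] | None:
    """Sub-grid apex (m/z, intensity) within ``center +- tol``.

    Three-point parabolic interpolation around the maximum sample; falls
    back to the raw maximum at window edges.
    """
    mz, inten = spec.slice(center - tol, center + tol)
    if mz.size < 3:
        return None
    k = int(np.argmax(inten))
    if k == 0 or k == mz.size - 1:
        return float(mz[k]), float(inten[k])
    y0, y1, y2 = inten[k - 1], inten[k], inten[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a local maximum of the parabola
        return float(mz[k]), float(inten[k])
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (mz[k + 1] - mz[k - 1])
    return float(mz[k] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def recalibrate(
    spec: Spectrum,
    calibrants: list[float] | np.ndarray,
    snr_min: float = SNR_MIN,
    min_found: int = 5,
    search_tol: float = CALIBRANT_SEARCH_TOL,
    degree: int = 2,
    flank: float = DEFAULT_FLANK,
    exclude_mz: np.ndarray | None = None,
) -> tuple[Spectrum, CalibrationResult]:
    """Recalibrate the m/z axis against a calibrant mass list.

    Each calibrant apex is searched within ``+-search_tol`` Da and
    accepted at S/N >= ``snr_min``; with at least ``min_found`` accepted
    calibrants a least-squares polynomial (default quadratic) mapping
    observed apexes to theoretical masses is applied to the whole axis.
    Otherwise the input spectrum is returned unchanged and flagged as
    excluded.
    """
    calibrants = np.sort(np.asarray(calibrants, dtype=float))
    if calibrants.size < min_found:
        raise PreprocessError(
            f"only {calibrants.size} calibrant masses supplied, need at least {min_found}"
        )
    fits: list[CalibrantFit] = []
    obs, theo = [], []
    for c in calibrants:
        apex = _apex(spec, c, search_tol)
        if apex is None:
            fits.append(CalibrantFit(c, False, None, 0.0, None, None))
            continue
        mz_apex, inten_apex = apex
        bg, noise = estimate_background(spec, c, flank=flank, exclude_mz=exclude_mz)
        snr = (inten_apex - bg) / noise if noise > 0 else np.inf
        found = snr >= snr_min
        ppm_before = (mz_apex - c) / c * 1e6
        fits.append(CalibrantFit(c, bool(found), mz_apex, float(snr), ppm_before, None))
        if found:
            obs.append(mz_apex)
            theo.append(c)
    if len(obs) < min_found:
        result = CalibrationResult(
            coefficients=np.array([1.0, 0.0]),
            calibrants=fits,
            passed=False,
            reason=f"only {len(obs)} calibrants at S/N >= {snr_min} (need {min_found})",
        )
        return spec, result
    deg = min(degree, len(obs) - 1)
    coeffs = np.polyfit(np.asarray(obs), np.asarray(theo), deg)
    new_mz = np.polyval(coeffs, spec.mz)
    calibrated = Spectrum(new_mz, spec.intensity.copy(), sample_id=spec.sample_id)
    fits = [
        CalibrantFit(
            f.mass,
            f.found,
            f.observed,
            f.snr,
            f.residual_ppm_before,
            (np.polyval(coeffs, f.observed) - f.mass) / f.mass * 1e6 if f.found else None,
        )
        for f in fits
    ]
    return calibrated, CalibrationResult(coeffs, fits, passed=True)


# ---------------------------------------------------------------------------
# targeted extraction
# ---------------------------------------------------------------------------

@dataclass
class AnalyteExtraction:
    feature: GlycanFeature
    area: float  # background-subtracted, isotope-coverage-corrected total area
    isotopologue_areas: np.ndarray
    background: float  # local background level at the top isotopologue
    noise: float  # local RMS noise
    snr: float  # S/N of the most abundant isotopologue apex
    qc_pass: bool  # snr > 9
    out_of_range: bool = False

    @property
    def name(self) -> str:
        return self.feature.name


INTERFERENCE_MIN_ABUNDANCE = 0.10  # pattern share above which a foreign isotopologue taints a window
INTERFERENCE_DISTANCE = 0.5  # Da within which a foreign isotopologue taints a window


def extract_feature(
    spec: Spectrum,
    feature: GlycanFeature,
    coverage: float = DEFAULT_COVERAGE,
    tol: float = DEFAULT_TOL,
    flank: float = DEFAULT_FLANK,
    exclude_mz: np.ndarray | None = None,
    snr_min: float = SNR_MIN,
    interference_mz: np.ndarray | None = None,
) -> AnalyteExtraction:
    """Integrate one feature's isotopic envelope with background subtraction.

    Per isotopologue the area is the sum of (intensity - background),
    floored at zero per point, over ``+-tol`` Da; the total is divided by
    the covered fraction of the isotope distribution so that envelopes
    truncated at ``coverage`` remain comparable across features.

    Isotopologue windows lying within ``INTERFERENCE_DISTANCE`` of a
    major isotopologue of *another* listed feature (``interference_mz``)
    are skipped and the coverage correction uses only the clean windows
    — e.g. O-acetylated species sit 4.03 Da below their
    ethyl-esterified partners, so their 5th isotopologue coincides with
    the partner's monoisotopic peak and cannot be integrated.  S/N is
    computed at the apex of the most abundant clean isotopologue.
    """
    offsets, abunds, _ = isotope_envelope(elemental_formula(feature.composition), coverage)
    centers = feature.mz + np.asarray(offsets)
    abunds = np.asarray(abunds)
    if centers[0] > spec.mz[-1] or centers[-1] < spec.mz[0]:
        return AnalyteExtraction(
            feature, 0.0, np.zeros(len(centers)), 0.0, 0.0, 0.0, False, out_of_range=True
        )
    clean = np.ones(centers.size, dtype=bool)
    if interference_mz is not None and len(interference_mz) > 0:
        inter = np.asarray(interference_mz)
        for i, c in enumerate(centers):
            if np.min(np.abs(inter - c)) < INTERFERENCE_DISTANCE:
                clean[i] = False
    if not clean.any():
        return AnalyteExtraction(
            feature, 0.0, np.zeros(len(centers)), 0.0, 0.0, 0.0, False, out_of_range=True
        )
    areas = np.zeros(centers.size)
    top = int(np.argmax(np.where(clean, abunds, -1.0)))
    bg_top, noise_top, snr = 0.0, 0.0, 0.0
    for i, c in enumerate(centers):
        if not clean[i]:
            continue
        bg, noise = estimate_background(spec, c, flank=flank, exclude_mz=exclude_mz)
        mz_w, int_w = spec.slice(c - tol, c + tol)
        if mz_w.size == 0:
            continue
        dx = np.empty_like(mz_w)
        dx[1:] = np.diff(mz_w)
        dx[0] = dx[1] if mz_w.size > 1 else 0.0
        areas[i] = float(np.sum(np.clip(int_w - bg, 0.0, None) * dx))
        if i == top:
            bg_top, noise_top = bg, noise
            apex = _apex(spec, c, tol)
            if apex is not None and noise > 0:
                snr = (apex[1] - bg) / noise
            elif apex is not None:
                snr = np.inf if apex[1] > bg else 0.0
    covered_clean = float(np.sum(abunds[clean]))
    total = float(np.sum(areas) / covered_clean)
    return AnalyteExtraction(
        feature,
        total,
        areas,
        bg_top,
        noise_top,
        float(snr),
        bool(snr > snr_min),
    )


def _interference_table(features: FeatureList) -> list[np.ndarray]:
    """Per feature: m/z of *other* features' major isotopologues.

    Majors are taken from the near-full (99.9 %) envelope, so that deep
    isotopologue tails of heavy interferers are not missed.
    """
    per_feature: list[np.ndarray] = []
    majors: list[np.ndarray] = []
    for f in features:
        offsets, abunds, _ = isotope_envelope(elemental_formula(f.composition), 0.999)
        arr = np.asarray(offsets) + f.mz
        majors.append(arr[np.asarray(abunds) >= INTERFERENCE_MIN_ABUNDANCE * np.sum(abunds)])
    for i in range(len(majors)):
        others = [m for j, m in enumerate(majors) if j != i]
        per_feature.append(np.sort(np.concatenate(others)) if others else np.empty(0))
    return per_feature


def extract_all(
    spec: Spectrum,
    features: FeatureList,
    coverage: float = DEFAULT_COVERAGE,
    tol: float = DEFAULT_TOL,
    flank: float = DEFAULT_FLANK,
    exclude_mz: np.ndarray | None = None,
    snr_min: float = SNR_MIN,
) -> list[AnalyteExtraction]:
    """Extract every feature of the list; warns on overlapping targets."""
    mzs = [f.mz for f in features]
    for a, b, d in zip(features, list(features)[1:], np.diff(mzs)):
        if d < 2 * tol:
            warnings.warn(
                f"features {a.name} and {b.name} are {d:.3f} Da apart; "
                f"integration windows (+-{tol} Da) overlap",
                stacklevel=2,
            )
    if exclude_mz is None:
        exclude_mz = known_peak_positions(features)
    interference = _interference_table(features)
    return [
        extract_feature(spec, f, coverage, tol, flank, exclude_mz, snr_min, inter)
        for f, inter in zip(features, interference)
    ]


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCResult:
    passed: bool
    fraction: float  # analyte-quality fraction: area share of features with S/N > 9
    reason: str = ""


def qc_spectrum(
    extractions: list[AnalyteExtraction],
    min_fraction: float = QC_MIN_FRACTION,
    snr_min: float = SNR_MIN,
) -> QCResult:
    """Spectrum-level QC on the share of analyte area above the S/N cut."""
    if not extractions:
        raise PreprocessError("no extractions supplied")
    total = sum(e.area for e in extractions)
    if total <= 0:
        return QCResult(False, 0.0, "total analyte area is zero")
    good = sum(e.area for e in extractions if e.snr > snr_min)
    fraction = good / total
    if fraction >= min_fraction:
        return QCResult(True, fraction)
    return QCResult(
        False, fraction, f"only {100 * fraction:.1f} % of analyte area above S/N {snr_min:g}"
    )


@dataclass
class GlycomeProfile:
    """Per-sample relative abundances (%), summing to 100."""

    abundances: pd.Series  # index: feature name, values: percent of total area
    sample_id: str = ""
    analyte_quality_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isclose(self.abundances.sum(), 100.0, atol=1e-9):
            raise PreprocessError(
                f"profile abundances sum to {self.abundances.sum()!r}, expected 100"
            )
        if (self.abundances < 0).any():
            raise PreprocessError("negative relative abundance")

    def __getitem__(self, name: str) -> float:
        return float(self.abundances[name])


def normalize_profile(
    extractions: list[AnalyteExtraction], sample_id: str = "", quality_fraction: float = float("nan")
) -> GlycomeProfile:
    """Total-area normalization: relative abundance in percent per feature."""
    areas = pd.Series({e.name: e.area for e in extractions}, dtype=float)
    total = areas.sum()
    if total <= 0:
        raise PreprocessError("cannot normalize: total analyte area is zero")
    return GlycomeProfile(100.0 * areas / total, sample_id, quality_fraction)


@dataclass
class SpectrumReport:
    sample_id: str
    calibration: CalibrationResult | None
    qc: QCResult | None
    included: bool
    reason: str = ""


def process_spectrum(
    spec: Spectrum,
    features: FeatureList,
    calibrants: list[float] | np.ndarray,
    snr_min: float = SNR_MIN,
    min_found: int = 5,
    min_fraction: float = QC_MIN_FRACTION,
    coverage: float = DEFAULT_COVERAGE,
    tol: float = DEFAULT_TOL,
    flank: float = DEFAULT_FLANK,
) -> tuple[GlycomeProfile | None, SpectrumReport]:
    """Full per-spectrum pipeline: recalibrate, extract, QC, normalize.

    Returns ``(profile, report)``; the profile is None when the spectrum
    is excluded (calibration failure or analyte-quality QC failure).
    """
    exclude = known_peak_positions(features, calibrants)
    calibrated, cal = recalibrate(
        spec, calibrants, snr_min=snr_min, min_found=min_found, exclude_mz=exclude
    )
    if not cal.passed:
        return None, SpectrumReport(spec.sample_id, cal, None, False, f"calibration: {cal.reason}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # overlap warnings already raised at list build
        extractions = extract_all(
            calibrated, features, coverage=coverage, tol=tol, flank=flank,
            exclude_mz=exclude, snr_min=snr_min,
        )
    qc = qc_spectrum(extractions, min_fraction=min_fraction, snr_min=snr_min)
    if not qc.passed:
        return None, SpectrumReport(spec.sample_id, cal, qc, False, f"qc: {qc.reason}")
    profile = normalize_profile(extractions, spec.sample_id, qc.fraction)
    return profile, SpectrumReport(spec.sample_id, cal, qc, True)
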