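"""Synthetic study generator: ground-truth glycome profiles and rendered
MALDI-TOF spectra for a zymosan-induced-peritonitis time course.

The generator produces what the real study measures but does not
deposit: per-animal glycome profiles on a 7-point time grid (0-72 h)
for a zymosan-challenged (ZIP) and a vehicle (control) group, plus
reflectron-positive MALDI-TOF profile spectra rendered from them.

Two layers of ground truth:

* **profile layer** — a baseline relative-abundance profile whose
  derived traits match the baseline mouse fluids (complex-type > 90 %,
  ~87 % diantennary, ~30 % fucosylated, NeuGc a2-6 per antenna ~79 %,
  a2-3 ~18 %, acetylation ~8 %, branching sialylation ~6 %), modified
  over time in the ZIP group by reallocating abundance between
  biologically paired features (fucosylated -> afucosylated,
  acetylated -> plain, disialylated-antenna gain), which keeps every
  profile realizable and mirrors the glycan-level drivers of the
  trait changes.  Between-animal variation is logistic-normal.
* **spectrum layer** — Gaussian isotopic envelopes with area
  proportional to abundance on a sloped baseline with additive
  Gaussian noise, spiked calibrant peaks, and a smooth ppm-level
  calibration distortion of the m/z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import elemental_formula, isotope_envelope
from .features import FeatureList, enumerate_default_features
from .io import SampleRecord, Spectrum, TIME_GRID
from .preprocess import GlycomeProfile
from .traits import compute_traits

__all__ = [
    "BASELINE_PLASMA",
    "PERITONEAL_ADJUSTMENTS",
    "DEFAULT_CALIBRANTS",
    "Reallocation",
    "DEFAULT_ZIP_EFFECTS",
    "SyntheticStudyConfig",
    "SpectrumRenderConfig",
    "StudyData",
    "baseline_profile",
    "make_profile",
    "render_spectrum",
    "simulate_study",
    "SyntheticError",
]


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# baseline profile (percent of total; sums to 100)
# ---------------------------------------------------------------------------

#: Plasma baseline at 0 h.  Chosen so that the derived traits land on the
#: baseline mouse values: high-mannose 0.9 %, hybrid 0.6 %, complex 98.5 %
#: split 2.6/87.8/9.1/0.5 % mono/di/tri/tetraantennary, fucosylation
#: ~29 %, acetylation ~7.6 %, branching sialylation ~6.4 %, NeuGc per
#: antenna ~79 % (a2-6) and ~19 % (a2-3).
BASELINE_PLASMA: dict[str, float] = {
    # high-mannose
    "H5N2": 0.35, "H6N2": 0.25, "H7N2": 0.15, "H8N2": 0.10, "H9N2": 0.05,
    # hybrid
    "H5N3Ge1": 0.40, "H6N3": 0.20,
    # monoantennary / truncated
    "H3N3Ge1": 0.60, "H4N3Ge1": 1.40, "H4N3": 0.56,
    # diantennary
    "H5N4Ge2": 28.61,
    "H5N4Ge1Gl1": 13.16,
    "H5N4Gl2": 2.00,
    "H5N4Ge2Gl1": 4.20,
    "H4N4Ge2Gl1": 1.60,
    "H5N4Ge1": 2.00,
    "H4N4Ge1": 1.50,
    "H5N4E1": 0.35,
    "H5N4L1": 0.25,
    "H5N4F1Ge2": 18.00,
    "H5N4F1Ge1Gl1": 6.00,
    "H5N4F1Ge1": 1.00,
    "H4N4F2Gl1": 0.12,
    "H5N4F2E1": 0.10,
    "H5N4Ge2Ac1": 2.60,
    "H5N4Ge2Ac2": 0.80,
    "H5N4F1Ge2Ac1": 2.20,
    "H5N4Ge1Gl1Ac1": 1.40,
    "H5N4F1Ge1Gl1Ac1": 0.60,
    # triantennary
    "H6N5Ge2Gl1": 3.00,
    "H6N5Ge1Gl2": 2.20,
    "H6N5Ge3": 1.56,
    "H6N5Ge2Gl2": 0.60,
    "H6N5F1Ge1": 1.00,
    "H6N5F1": 0.20,
    "H5N5Ge2": 0.40,
    # tetraantennary
    "H7N6Ge2Gl2": 0.30,
    "H7N6Ge1Gl2": 0.19,
}

#: Multiplicative adjustments turning the plasma baseline into the
#: peritoneal-fluid one (higher high-mannose, acetylation and branching
#: sialylation), renormalized afterwards.
PERITONEAL_ADJUSTMENTS: dict[str, float] = {
    "H5N2": 1.56, "H6N2": 1.56, "H7N2": 1.56, "H8N2": 1.56, "H9N2": 1.56,
    "H5N4Ge2Ac1": 1.45, "H5N4Ge2Ac2": 1.45, "H5N4F1Ge2Ac1": 1.45,
    "H5N4Ge1Gl1Ac1": 1.45, "H5N4F1Ge1Gl1Ac1": 1.45,
    "H5N4Ge2Gl1": 1.28, "H4N4Ge2Gl1": 1.28, "H6N5Ge2Gl2": 1.28,
}


def baseline_profile(fluid: str = "plasma") -> pd.Series:
    """Baseline relative-abundance profile (percent, sums to 100)."""
    s = pd.Series(BASELINE_PLASMA, dtype=float)
    if fluid == "peritoneal":
        for name, factor in PERITONEAL_ADJUSTMENTS.items():
            s[name] *= factor
        s = 100.0 * s / s.sum()
    elif fluid != "plasma":
        raise SyntheticError(f"unknown fluid {fluid!r}")
    return s


# ---------------------------------------------------------------------------
# group x time effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reallocation:
    """Move abundance from one feature to another, by time point (pp)."""

    source: str
    target: str
    amount_pp: dict[int, float]  # time_h -> percentage points moved

    def amount(self, time_h: int) -> float:
        return float(self.amount_pp.get(time_h, 0.0))


#: ZIP trajectories: fucosylation declines to its minimum at 24 h and
#: stays flat; a2-3 NeuGc / branching / total sialylation rise to a peak
#: at 48 h then decline; acetylation drops; triantennary species rise.
#: All effects are zero at 0-4 h.
DEFAULT_ZIP_EFFECTS: tuple[Reallocation, ...] = (
    Reallocation(
        "H5N4F1Ge2", "H5N4Ge2",
        {12: 4.0, 24: 8.0, 48: 8.0, 72: 8.0},
    ),
    Reallocation(
        "H5N4F1Ge2Ac1", "H5N4F1Ge2",
        {12: 0.7, 24: 1.3, 48: 1.3, 72: 1.0},
    ),
    Reallocation(
        "H5N4Ge2", "H4N4Ge2Gl1",
        {12: 3.0, 24: 5.0, 48: 7.0, 72: 4.5},
    ),
    Reallocation(
        "H5N4Ge2", "H6N5Ge2Gl1",
        {12: 1.0, 24: 2.0, 48: 2.5, 72: 1.5},
    ),
)


@dataclass
class SyntheticStudyConfig:
    """Study design and profile-level generative parameters."""

    fluid: str = "peritoneal"
    effects: tuple[Reallocation, ...] = DEFAULT_ZIP_EFFECTS
    noise_sigma: float = 0.06  # logistic-normal SD on log-abundances
    n_zip: int = 6
    n_control: int = 3
    time_grid: tuple[int, ...] = TIME_GRID
    experiment: int = 1
    seed: int = 20160229

    def __post_init__(self) -> None:
        base = baseline_profile(self.fluid)
        if not np.isclose(base.sum(), 100.0):
            raise SyntheticError("baseline must sum to 100")
        for t in self.time_grid:
            self.expected_profile("ZIP", t)  # raises if any abundance < 0

    def expected_profile(self, group: str, time_h: int) -> pd.Series:
        """Noise-free profile for a group/time cell (percent)."""
        prof = baseline_profile(self.fluid)
        if group == "ZIP":
            for eff in self.effects:
                amt = eff.amount(time_h)
                if amt == 0.0:
                    continue
                for name in (eff.source, eff.target):
                    if name not in prof.index:
                        raise SyntheticError(f"effect references unknown feature {name!r}")
                prof[eff.source] -= amt
                prof[eff.target] += amt
                if prof[eff.source] < 0:
                    raise SyntheticError(
                        f"effect {eff.source}->{eff.target} at {time_h} h drives "
                        f"{eff.source} below zero"
                    )
        elif group != "control":
            raise SyntheticError(f"unknown group {group!r}")
        return prof


def make_profile(
    config: SyntheticStudyConfig,
    group: str,
    time_h: int,
    rng: np.random.Generator,
    features: FeatureList | None = None,
    sample_id: str = "",
) -> tuple[GlycomeProfile, pd.Series]:
    """One animal's true profile and derived traits.

    Between-animal variation is logistic-normal: Gaussian perturbation of
    log-abundances followed by softmax renormalization, which preserves
    the 100 % simplex constraint.
    """
    expected = config.expected_profile(group, time_h)
    logs = np.log(expected.to_numpy())
    if config.noise_sigma > 0:
        logs = logs + rng.normal(0.0, config.noise_sigma, size=logs.size)
    vals = np.exp(logs)
    profile = GlycomeProfile(
        pd.Series(100.0 * vals / vals.sum(), index=expected.index),
        sample_id=sample_id,
    )
    feats = features if features is not None else _default_features()
    return profile, compute_traits(profile, feats)


_FEATURES_CACHE: FeatureList | None = None


def _default_features() -> FeatureList:
    global _FEATURES_CACHE
    if _FEATURES_CACHE is None:
        _FEATURES_CACHE = enumerate_default_features()
    return _FEATURES_CACHE


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------

#: Calibrant set: peptide-like masses spanning the glycan m/z range,
#: spiked into every rendered spectrum (emulating the calibration
#: standard mixed into the matrix), all > 0.5 Da away from any default
#: feature isotopologue.
DEFAULT_CALIBRANTS: tuple[float, ...] = (
    1046.542, 1296.685, 1347.736, 1619.823, 2093.087, 2455.530, 3147.471, 3494.651,
)


@dataclass
class SpectrumRenderConfig:
    """Acquisition-layer parameters of the rendered spectra."""

    mz_start: float = 900.0
    mz_end: float = 3800.0
    mz_step: float = 0.02
    fwhm: float = 0.15  # Da; reflectron-TOF peak width
    fwhm_slope: float = 0.0  # Da of extra FWHM per Da above 2000
    intensity_scale: float = 100.0  # envelope area units per percent abundance
    baseline_level: float = 20.0
    baseline_slope: float = -0.004  # per Da, from mz_start
    noise_sigma: float = 2.0
    # calibration distortion: ppm(m) = c0 + c1*u + c2*u^2, u = (m-2350)/1450
    distortion_ppm: tuple[float, float, float] = (20.0, 15.0, 10.0)
    calibrants: tuple[float, ...] = DEFAULT_CALIBRANTS
    calibrant_area: float = 300.0
    envelope_coverage: float = 0.999

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise SyntheticError("FWHM must be positive")
        if self.noise_sigma < 0:
            raise SyntheticError("noise sigma must be >= 0")

    def ppm_at(self, mz: np.ndarray) -> np.ndarray:
        c0, c1, c2 = self.distortion_ppm
        u = (np.asarray(mz) - 2350.0) / 1450.0
        return c0 + c1 * u + c2 * u**2


def _add_gaussian(grid: np.ndarray, intensity: np.ndarray, center: float,
                  area: float, sigma: float) -> None:
    lo = np.searchsorted(grid, center - 5 * sigma)
    hi = np.searchsorted(grid, center + 5 * sigma)
    if hi <= lo:
        return
    x = grid[lo:hi]
    intensity[lo:hi] += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2
    )


def render_spectrum(
    profile: GlycomeProfile | pd.Series,
    features: FeatureList,
    config: SpectrumRenderConfig | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> Spectrum:
    """Render a profile as a reflectron-positive MALDI-TOF spectrum.

    Each feature's isotopic envelope is drawn as Gaussians whose total
    area is proportional to its relative abundance (isotopologue areas
    follow the raw isotope distribution, truncated at
    ``envelope_coverage``); calibrant peaks, a sloped baseline, additive
    Gaussian noise and the ppm-level axis distortion are applied on top.
    """
    cfg = config or SpectrumRenderConfig()
    abund = profile.abundances if isinstance(profile, GlycomeProfile) else profile
    grid = np.arange(cfg.mz_start, cfg.mz_end, cfg.mz_step)
    intensity = cfg.baseline_level + cfg.baseline_slope * (grid - cfg.mz_start)
    if np.any(intensity < 0):
        raise SyntheticError("baseline goes negative over the m/z range")
    sig = cfg.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for name, a in abund.items():
        if a <= 0:
            continue
        f = features[name]
        offsets, raw, _ = isotope_envelope(elemental_formula(f.composition),
                                           cfg.envelope_coverage)
        sigma_f = sig + cfg.fwhm_slope * max(0.0, f.mz - 2000.0) / 2.3548
        for off, p in zip(offsets, raw):
            _add_gaussian(grid, intensity, f.mz + off, a * cfg.intensity_scale * p, sigma_f)
    for c in cfg.calibrants:
        _add_gaussian(grid, intensity, c, cfg.calibrant_area, sig)
    if cfg.noise_sigma > 0:
        if rng is None:
            raise SyntheticError("an rng is required when noise_sigma > 0")
        intensity = intensity + rng.normal(0.0, cfg.noise_sigma, size=intensity.size)
        intensity = np.clip(intensity, 0.0, None)
    observed_mz = grid * (1.0 + cfg.ppm_at(grid) * 1e-6)
    return Spectrum(observed_mz, intensity, sample_id=sample_id)


# ---------------------------------------------------------------------------
# full study simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    metadata: pd.DataFrame  # one row per sample
    records: list[SampleRecord]
    spectra: list[Spectrum] | None  # aligned with records; None if not rendered
    truth_profiles: pd.DataFrame  # features x samples (percent)
    truth_traits: pd.DataFrame  # samples x traits


def simulate_study(
    config: SyntheticStudyConfig | None = None,
    render_config: SpectrumRenderConfig | None = None,
    features: FeatureList | None = None,
    render: bool = True,
) -> StudyData:
    """Simulate the full factorial study: groups x time grid x animals.

    Deterministic under ``config.seed``.  With ``render=False`` only the
    profile-layer ground truth is produced (fast path for statistical
    simulations).
    """
    cfg = config or SyntheticStudyConfig()
    feats = features if features is not None else _default_features()
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_zip == 0 and cfg.n_control == 0:
        import warnings

        warnings.warn("n=0 per group: simulating an empty study", stacklevel=2)
    records: list[SampleRecord] = []
    spectra: list[Spectrum] | None = [] if render else None
    profiles: dict[str, pd.Series] = {}
    traits_rows: dict[str, pd.Series] = {}
    for group, n in (("ZIP", cfg.n_zip), ("control", cfg.n_control)):
        for time_h in cfg.time_grid:
            for rep in range(1, n + 1):
                sid = f"{group}_e{cfg.experiment}_t{time_h:02d}_r{rep}"
                rec = SampleRecord(sid, group, cfg.fluid, time_h, cfg.experiment, rep)
                profile, traits = make_profile(cfg, group, time_h, rng, feats, sid)
                records.append(rec)
                profiles[sid] = profile.abundances
                traits_rows[sid] = traits
                if render:
                    spectra.append(
                        render_spectrum(profile, feats, render_config, rng, sid)
                    )
    metadata = pd.DataFrame([r.__dict__ for r in records])
    truth_profiles = pd.DataFrame(profiles)
    truth_traits = pd.DataFrame(traits_rows).T
    return StudyData(metadata, records, spectra, truth_profiles, truth_traits)
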