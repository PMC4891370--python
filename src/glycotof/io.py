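"""Reading and writing profile spectra (two-column text) and sample metadata."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SampleRecord",
    "SpectrumFormatError",
    "MetadataError",
    "read_xy_spectrum",
    "write_xy_spectrum",
    "read_metadata",
    "write_metadata",
    "TIME_GRID",
    "GROUPS",
    "FLUIDS",
]

TIME_GRID = (0, 2, 4, 12, 24, 48, 72)
GROUPS = ("ZIP", "control")
FLUIDS = ("plasma", "peritoneal")

METADATA_COLUMNS = ["sample_id", "group", "fluid", "time_h", "experiment", "replicate"]


class SpectrumFormatError(ValueError):
    pass


class MetadataError(ValueError):
    pass


@dataclass
class Spectrum:
    """One profile acquisition: paired m/z and intensity arrays."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectrumFormatError(
                f"mz and intensity must be 1-D arrays of equal length "
                f"(got {self.mz.shape} vs {self.intensity.shape})"
            )
        if np.any(np.diff(self.mz) <= 0):
            raise SpectrumFormatError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise SpectrumFormatError("negative intensities; apply the clipping policy first")

    def __len__(self) -> int:
        return self.mz.size

    def slice(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        """Views of (mz, intensity) restricted to [lo, hi]."""
        i, j = np.searchsorted(self.mz, (lo, hi))
        return self.mz[i:j], self.intensity[i:j]


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str
    fluid: str
    time_h: int
    experiment: int = 1
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise MetadataError(f"{self.sample_id}: unknown group {self.group!r} (expected {GROUPS})")
        if self.fluid not in FLUIDS:
            raise MetadataError(f"{self.sample_id}: unknown fluid {self.fluid!r} (expected {FLUIDS})")
        if self.time_h not in TIME_GRID:
            raise MetadataError(
                f"{self.sample_id}: time_h={self.time_h} not on the study grid {TIME_GRID}"
            )
        if self.experiment not in (1, 2):
            raise MetadataError(f"{self.sample_id}: experiment must be 1 or 2")


def read_xy_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (m/z, intensity) text spectrum.

    Accepts whitespace- or comma-delimited numeric rows; lines starting
    with ``#`` are comments.  Non-monotone m/z values are sorted (with a
    warning) and negative intensities clipped to zero (with a warning).
    """
    path = Path(path)
    mzs: list[float] = []
    ints: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    mz = np.array(mzs)
    intensity = np.array(ints)
    if mz.size == 0:
        raise SpectrumFormatError(f"{path}: no data rows")
    if np.any(np.diff(mz) <= 0):
        warnings.warn(f"{path}: m/z axis not strictly increasing; sorting", stacklevel=2)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        keep = np.concatenate([[True], np.diff(mz) > 0])
        mz, intensity = mz[keep], intensity[keep]
    if np.any(intensity < 0):
        warnings.warn(f"{path}: negative intensities clipped to 0", stacklevel=2)
        intensity = np.clip(intensity, 0.0, None)
    return Spectrum(mz, intensity, sample_id=sample_id or path.stem)


def write_xy_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text, lossless for float64 round trips."""
    np.savetxt(path, np.column_stack([spec.mz, spec.intensity]), fmt="%.17g")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read and validate a sample-metadata CSV (one row per spectrum)."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata CSV {path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    group=str(row["group"]),
                    fluid=str(row["fluid"]),
                    time_h=int(row["time_h"]),
                    experiment=int(row["experiment"]),
                    replicate=int(row["replicate"]),
                )
            )
        except (MetadataError, ValueError) as exc:
            raise MetadataError(f"metadata CSV {path} row {i + 2}: {exc}") from exc
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise MetadataError(f"metadata CSV {path}: duplicate sample_id {dupes}")
    return records


def write_metadata(records: list[SampleRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records])[METADATA_COLUMNS].to_csv(path, index=False)
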