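"""Shared domain types for angular-interrogation SPR data.

These containers are the exchange objects of the whole pipeline: the
detector geometry maps pixel columns to incidence angles, a raw image set
holds the dark/TE/TM frame triplet, and an ``SPRCurve`` is the universal
angle-vs-reflectance-ratio table that the simulator produces, the image
pipeline extracts and the fitting layer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DetectorGeometry", "RawImageSet", "SPRCurve"]


@dataclass(frozen=True)
class DetectorGeometry:
    """Linear pixel-column -> incidence-angle map of the detector.

    The wedge-shaped beam spreads a fixed angular window across the detector
    columns, so the map is linear: pixel ``i`` sees
    ``start_deg + i * span_deg / n_pixels``.

    Parameters
    ----------
    n_pixels : int
        Number of detector columns (>= 2).
    span_deg : float
        Total angular window in degrees (> 0).
    start_deg : float
        Incidence angle of pixel 0, in degrees. An instrument calibration;
        curves may also be kept on a raw pixel axis by using
        ``start_deg=0, span_deg=n_pixels`` (one "degree" per pixel).
    """

    n_pixels: int
    span_deg: float
    start_deg: float

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError(f"n_pixels must be >= 2, got {self.n_pixels}")
        if not self.span_deg > 0:
            raise ValueError(f"span_deg must be > 0, got {self.span_deg}")

    @property
    def resolution_deg(self) -> float:
        """Angular width of one pixel in degrees."""
        return self.span_deg / self.n_pixels

    def pixel_to_angle(self, pixel_index):
        """Incidence angle of a pixel column (scalar or array)."""
        idx = np.asarray(pixel_index)
        if np.any(idx < 0) or np.any(idx >= self.n_pixels):
            raise ValueError(
                f"pixel index out of range [0, {self.n_pixels}): {pixel_index}"
            )
        angle = self.start_deg + idx * self.resolution_deg
        return float(angle) if np.isscalar(pixel_index) else angle

    def angles(self) -> np.ndarray:
        """Angle of every pixel column, strictly increasing."""
        return self.start_deg + np.arange(self.n_pixels) * self.resolution_deg


@dataclass(frozen=True)
class RawImageSet:
    """Dark / TE-mode / TM-mode detector frame triplet.

    The dark frame is captured with the source off; TE and TM frames with the
    polarizer in s- and p-orientation. All three must share one shape and
    contain finite, non-negative intensities.
    """

    dark: np.ndarray
    te: np.ndarray
    tm: np.ndarray

    def __post_init__(self) -> None:
        dark = np.asarray(self.dark, dtype=float)
        te = np.asarray(self.te, dtype=float)
        tm = np.asarray(self.tm, dtype=float)
        if not (dark.shape == te.shape == tm.shape):
            raise ValueError(
                f"frame shapes differ: dark {dark.shape}, te {te.shape}, tm {tm.shape}"
            )
        if dark.ndim != 2:
            raise ValueError(f"frames must be 2-D, got {dark.ndim}-D")
        for name, arr in (("dark", dark), ("te", te), ("tm", tm)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} frame contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} frame contains negative intensities")
        object.__setattr__(self, "dark", dark)
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "tm", tm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dark.shape


@dataclass(frozen=True)
class SPRCurve:
    """Reflectance-ratio curve on a strictly increasing angle axis.

    ``values[i]`` is the TM/TE reflectance ratio at incidence angle
    ``angles_deg[i]``. The axis may be true degrees or raw pixel indices;
    all downstream operations only rely on strict monotonicity.
    """

    angles_deg: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if angles.ndim != 1 or values.ndim != 1:
            raise ValueError("angles and values must be 1-D")
        if angles.size != values.size:
            raise ValueError(
                f"length mismatch: {angles.size} angles vs {values.size} values"
            )
        if angles.size < 3:
            raise ValueError(f"curve needs >= 3 points, got {angles.size}")
        if not np.all(np.isfinite(angles)) or not np.all(np.isfinite(values)):
            raise ValueError("curve contains non-finite entries")
        if not np.all(np.diff(angles) > 0):
            bad = int(np.flatnonzero(np.diff(angles) <= 0)[0]) + 1
            raise ValueError(f"angles not strictly increasing at row {bad}")
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.angles_deg.size

    @property
    def step_deg(self) -> float:
        """Median angular spacing between samples."""
        return float(np.median(np.diff(self.angles_deg)))

    @property
    def angle_range(self) -> tuple[float, float]:
        return float(self.angles_deg[0]), float(self.angles_deg[-1])
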