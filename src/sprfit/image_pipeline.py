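"""Turn dark/TE/TM detector frames into an SPR curve on an angle axis.

The instrument records three frames: a dark frame (source off) and the TE-
and TM-polarized reflection images. Normalization removes the dark offset
and the illumination profile in one step,

    ratio = (TM - dark) / (TE - dark),

and the curve is the column-wise mean of a horizontal band of rows (100 by
default) of the ratio image, plotted against each column's incidence angle.
"""

from __future__ import annotations

import numpy as np

from .core import DetectorGeometry, RawImageSet, SPRCurve

__all__ = [
    "RawImageSet",
    "SPRCurve",
    "normalize_images",
    "extract_curve",
    "pixel_to_angle",
    "default_row_band",
]

DEFAULT_BAND_HEIGHT = 100


def normalize_images(raw: RawImageSet, denom_floor: float | None = None) -> np.ma.MaskedArray:
    """Dark-subtracted TM over dark-subtracted TE, with unstable pixels masked.

    Pixels whose TE - dark denominator is at or below ``denom_floor`` are
    masked and excluded from downstream averaging instead of producing
    blow-up ratios. The default floor is 1e-6 of the TE frame's dynamic
    range after dark subtraction.
    """
    te_sub = raw.te - raw.dark
    tm_sub = raw.tm - raw.dark
    if denom_floor is None:
        denom_floor = 1e-6 * float(np.max(te_sub) - min(0.0, float(np.min(te_sub))))
        denom_floor = max(denom_floor, np.finfo(float).tiny)
    elif denom_floor <= 0:
        raise ValueError(f"denom_floor must be > 0, got {denom_floor}")
    invalid = te_sub <= denom_floor
    safe = np.where(invalid, 1.0, te_sub)
    ratio = tm_sub / safe
    return np.ma.masked_array(ratio, mask=invalid)


def default_row_band(n_rows: int, height: int = DEFAULT_BAND_HEIGHT) -> tuple[int, int]:
    """Centered inclusive row interval of the given height (clipped to image).

    On the instrument's 1024-row frames the default covers rows 462-561.
    """
    height = min(height, n_rows)
    lo = (n_rows - height) // 2
    return lo, lo + height - 1


def extract_curve(
    ratio_image: np.ndarray | np.ma.MaskedArray,
    row_band: tuple[int, int] | None = None,
    geometry: DetectorGeometry | None = None,
) -> SPRCurve:
    """Column-wise mean of a row band of the ratio image, on the angle axis.

    Parameters
    ----------
    ratio_image : 2-D array or masked array
        Output of :func:`normalize_images`.
    row_band : (int, int), optional
        Inclusive row interval to average. Defaults to a centered band of
        100 rows.
    geometry : DetectorGeometry, optional
        Pixel-to-angle calibration. If omitted, the curve is returned on a
        raw pixel-index axis.

    Raises
    ------
    ValueError
        If the band lies outside the image or some column has no valid
        pixel inside the band.
    """
    img = np.ma.asarray(ratio_image)
    if img.ndim != 2:
        raise ValueError(f"ratio image must be 2-D, got {img.ndim}-D")
    n_rows, n_cols = img.shape
    if row_band is None:
        row_band = default_row_band(n_rows)
    lo, hi = row_band
    if not (0 <= lo <= hi < n_rows):
        raise ValueError(f"row band {row_band} outside image with {n_rows} rows")
    band = img[lo : hi + 1, :]

    counts = band.count(axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(
            f"column {int(empty[0])} has no valid pixel in rows {lo}-{hi} "
            "(TE - dark at or below the denominator floor)"
        )
    values = np.asarray(band.mean(axis=0))

    if geometry is not None:
        if geometry.n_pixels != n_cols:
            raise ValueError(
                f"geometry has {geometry.n_pixels} pixels but image has {n_cols} columns"
            )
        angles = geometry.angles()
    else:
        angles = np.arange(n_cols, dtype=float)
    return SPRCurve(angles_deg=angles, values=values)


def pixel_to_angle(geometry: DetectorGeometry, pixel_index):
    """Incidence angle of a detector column: start + index * span / n_pixels."""
    return geometry.pixel_to_angle(pixel_index)
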