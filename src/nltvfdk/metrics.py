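"""Image-quality metrics: HU conversion, masked RMSE/correlation, ROI CNR.

RMSE and correlation are evaluated over a circular mask inside the
phantom (excluding surrounding air); CNR compares an insert ROI against a
background ROI using the pooled-standard-deviation convention

    CNR = |mean_roi - mean_bg| / sqrt((sigma_roi^2 + sigma_bg^2) / 2)

(a background-sigma denominator is also available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .backprojector import Volume

__all__ = [
    "ROISpec",
    "hu_convert",
    "masked_rmse",
    "masked_correlation",
    "cnr",
    "cylinder_mask",
    "roi_mask",
]


@dataclass(frozen=True)
class ROISpec:
    """Circular in-slice region: center (mm), slice index, radius (mm)."""

    center_x: float
    center_y: float
    slice_index: int
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("radius must be positive")


def hu_convert(vol: Volume, mu_water: float, mu_air: float = 0.0) -> Volume:
    """HU = 1000 (mu - mu_water) / (mu_water - mu_air)."""
    if not (mu_water > mu_air):
        raise ValueError("mu_water must exceed mu_air")
    hu = 1000.0 * (vol.values - mu_water) / (mu_water - mu_air)
    return Volume(hu, vol.voxel_size)


def _values(vol) -> np.ndarray:
    return vol.values if isinstance(vol, Volume) else np.asarray(vol, dtype=float)


def masked_rmse(vol, ref, mask) -> float:
    """Root-mean-square difference over the mask (units of the inputs)."""
    a, b = _values(vol), _values(ref)
    mask = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("volume, reference and mask shapes must match")
    if not mask.any():
        raise ValueError("empty mask")
    d = a[mask] - b[mask]
    return float(np.sqrt(np.mean(d * d)))


def masked_correlation(vol, ref, mask) -> float:
    """Pearson correlation of the two volumes over the mask."""
    a, b = _values(vol)[np.asarray(mask, dtype=bool)], _values(ref)[np.asarray(mask, dtype=bool)]
    if a.size == 0:
        raise ValueError("empty mask")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for constant masked values")
    return float(stats.pearsonr(a, b)[0])


def roi_mask(vol: Volume, roi: ROISpec) -> np.ndarray:
    """Boolean mask of a circular ROI in one slice of the volume."""
    nz, ny, nx = vol.shape
    if not (0 <= roi.slice_index < nz):
        raise ValueError("ROI slice outside the grid")
    x = vol.axis_coords(2)[None, :]
    y = vol.axis_coords(1)[:, None]
    disc = (x - roi.center_x) ** 2 + (y - roi.center_y) ** 2 <= roi.radius**2
    mask = np.zeros(vol.shape, dtype=bool)
    mask[roi.slice_index] = disc
    if not mask.any():
        raise ValueError("ROI does not cover any voxel")
    return mask


def cylinder_mask(
    vol: Volume,
    radius: float,
    half_height: float | None = None,
    center_x: float = 0.0,
    center_y: float = 0.0,
) -> np.ndarray:
    """Axis-aligned cylindrical mask (mm), used for the in-phantom region."""
    x = vol.axis_coords(2)[None, None, :]
    y = vol.axis_coords(1)[None, :, None]
    z = vol.axis_coords(0)[:, None, None]
    mask = (x - center_x) ** 2 + (y - center_y) ** 2 <= radius**2
    mask = np.broadcast_to(mask, vol.shape).copy()
    if half_height is not None:
        mask &= np.abs(z) <= half_height
    return mask


def cnr(vol: Volume, roi: ROISpec, background: ROISpec, denominator: str = "pooled") -> float:
    """Contrast-to-noise ratio between an insert ROI and a background ROI."""
    a = vol.values[roi_mask(vol, roi)]
    b = vol.values[roi_mask(vol, background)]
    if denominator == "pooled":
        sigma = np.sqrt((np.var(a) + np.var(b)) / 2.0)
    elif denominator == "background":
        sigma = np.std(b)
    else:
        raise ValueError("denominator must be 'pooled' or 'background'")
    if sigma == 0:
        raise ValueError("CNR undefined: zero noise estimate")
    return float(abs(a.mean() - b.mean()) / sigma)
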