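"""Gray-level discretization of in-mask intensities.

Equal-width binning over the in-mask intensity range (fixed bin count),
mapping intensities to integer gray levels 1..N_g.  The in-mask maximum
maps to N_g; a constant region maps every voxel to level 1.  Texture
matrices are built on these levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import ImageVolume, RoiMask, ValidationError


@dataclass
class QuantizedRoi:
    """Integer gray levels on the ROI's bounding-box crop.

    ``levels`` is 0 outside the mask and in 1..``n_bins`` inside.
    ``mask`` is the cropped binary mask; ``bin_edges`` the HU bin
    boundaries (``None`` for a constant region).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray | None

    @property
    def present_levels(self) -> np.ndarray:
        return np.unique(self.levels[self.mask])


def quantize(volume: ImageVolume, roi: RoiMask, n_bins: int = 32) -> QuantizedRoi:
    """Discretize ``volume`` within ``roi`` into ``n_bins`` equal-width levels."""
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if volume.shape != roi.mask.shape:
        raise ValidationError("mask shape differs from volume shape")
    if not roi.mask.any():
        raise ValidationError("empty mask")

    idx = np.argwhere(roi.mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    crop = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    mask = roi.mask[crop]
    values = volume.values[crop]

    vmin = float(values[mask].min())
    vmax = float(values[mask].max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
        return QuantizedRoi(levels=levels, mask=mask, n_bins=n_bins, bin_edges=None)
    width = (vmax - vmin) / n_bins
    lv = np.floor((values[mask] - vmin) / width).astype(np.int32) + 1
    np.clip(lv, 1, n_bins, out=lv)  # in-mask max falls on the last edge
    levels[mask] = lv
    edges = vmin + width * np.arange(n_bins + 1)
    return QuantizedRoi(levels=levels, mask=mask, n_bins=n_bins, bin_edges=edges)
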