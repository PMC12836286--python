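"""Conventional radiomics feature extraction (56 features per ROI)."""

from __future__ import annotations

import numpy as np

from ..core import ImageVolume, RoiMask, ValidationError
from .geometry import GEOMETRY_FEATURE_NAMES, geometry_features
from .intensity import INTENSITY_FEATURE_NAMES, intensity_features
from .quantize import QuantizedRoi, quantize
from .texture import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

#: Canonical order of the 56 conventional features: 9 intensity,
#: 7 geometry, 8 GLCM, 11 GLRLM, 16 GLSZM, 5 NGTDM.
CONVENTIONAL_FEATURE_NAMES: tuple[str, ...] = (
    INTENSITY_FEATURE_NAMES
    + GEOMETRY_FEATURE_NAMES
    + GLCM_FEATURE_NAMES
    + GLRLM_FEATURE_NAMES
    + GLSZM_FEATURE_NAMES
    + NGTDM_FEATURE_NAMES
)

assert len(CONVENTIONAL_FEATURE_NAMES) == 56


def extract_conventional(
    volume: ImageVolume, roi: RoiMask, n_bins: int = 32
) -> dict[str, float]:
    """Extract the 56 conventional features for one ROI.

    Returns an ordered name -> value mapping following
    :data:`CONVENTIONAL_FEATURE_NAMES`.  All values are finite;
    degenerate regions follow the documented texture conventions.
    """
    out: dict[str, float] = {}
    out.update(intensity_features(volume, roi))
    out.update(geometry_features(roi, volume.spacing))
    q = quantize(volume, roi, n_bins=n_bins)
    out.update(glcm_features(q))
    out.update(glrlm_features(q))
    out.update(glszm_features(q))
    out.update(ngtdm_features(q))
    ordered = {name: out[name] for name in CONVENTIONAL_FEATURE_NAMES}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValidationError(f"non-finite features: {bad}")
    return ordered


__all__ = [
    "CONVENTIONAL_FEATURE_NAMES",
    "QuantizedRoi",
    "extract_conventional",
    "geometry_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "intensity_features",
    "ngtdm_features",
    "quantize",
]
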