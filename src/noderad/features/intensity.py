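"""First-order intensity statistics of the in-mask HU values.

Nine features: minimum, maximum, mean, median, standard deviation, sum,
skewness, kurtosis and variance.  Moments are population (biased)
moments; kurtosis is excess kurtosis (Fisher).  Zero-variance regions
report 0 for standard deviation, skewness and kurtosis rather than NaN.
"""

from __future__ import annotations

import numpy as np

from ..core import ImageVolume, RoiMask, ValidationError

INTENSITY_FEATURE_NAMES = (
    "intensity_minimum",
    "intensity_maximum",
    "intensity_mean",
    "intensity_median",
    "intensity_std",
    "intensity_sum",
    "intensity_skewness",
    "intensity_kurtosis",
    "intensity_variance",
)


def intensity_features(volume: ImageVolume, roi: RoiMask) -> dict[str, float]:
    """Return the 9 intensity features of ``volume`` restricted to ``roi``."""
    if volume.shape != roi.mask.shape:
        raise ValidationError("mask shape differs from volume shape")
    x = volume.values[roi.mask]
    if x.size == 0:
        raise ValidationError("empty mask")
    mean = float(x.mean())
    var = float(x.var())  # population variance
    if var > 0.0:
        z = (x - mean) / np.sqrt(var)
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "intensity_minimum": float(x.min()),
        "intensity_maximum": float(x.max()),
        "intensity_mean": mean,
        "intensity_median": float(np.median(x)),
        "intensity_std": float(np.sqrt(var)),
        "intensity_sum": float(x.sum()),
        "intensity_skewness": skew,
        "intensity_kurtosis": kurt,
        "intensity_variance": var,
    }
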