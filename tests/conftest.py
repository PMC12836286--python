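import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles imports

from noderad.core import ImageVolume, RoiMask
from noderad.features.quantize import QuantizedRoi
from noderad.phantom import PhantomConfig
from noderad.pipeline import build_feature_table


def make_quantized(levels_2d_or_3d, n_bins=None) -> QuantizedRoi:
    """Build a QuantizedRoi directly from an integer level grid.

    2D inputs get a singleton third axis; zeros mark out-of-mask voxels.
    """
    levels = np.asarray(levels_2d_or_3d, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    mask = levels > 0
    if n_bins is None:
        n_bins = max(int(levels.max()), 2)
    return QuantizedRoi(levels=levels, mask=mask, n_bins=n_bins, bin_edges=None)


def volume_roi_from_values(values, spacing=(1.0, 1.0, 1.0)):
    """Volume + full mask over a (possibly 1D/2D) value grid."""
    arr = np.asarray(values, dtype=float)
    while arr.ndim < 3:
        arr = arr[..., None]
    return ImageVolume(arr, spacing), RoiMask(np.ones(arr.shape, bool))


@pytest.fixture(scope="session")
def small_cohort_table():
    """Feature table of a 30-patient phantom cohort (session-cached)."""
    return build_feature_table(PhantomConfig(n_patients=30, seed=5))


@pytest.fixture(scope="session")
def tiny_case():
    """A rendered 12-patient phantom cohort for structural tests."""
    from noderad.phantom import iter_cohort

    return list(iter_cohort(PhantomConfig(n_patients=12, seed=21)))
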