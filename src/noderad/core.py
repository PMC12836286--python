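"""Core in-memory containers shared across the pipeline.

The geometric frame is a 3D scalar grid (CT-like, in Hounsfield units)
with anisotropic voxel spacing in millimetres.  Regions of interest
(primary tumor, lymph nodes) are binary masks aligned voxel-for-voxel
with that grid.  Nodes additionally carry the anatomical metadata the
spatial features are built from: nodal level (I--VI), laterality, and
the pathology label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TUMOR_TYPES = ("base_of_tongue", "tonsil", "oropharynx", "larynx", "hypopharynx")
NODE_LEVELS = ("I", "II", "III", "IV", "V", "VI")
# Clinical sub-levels accepted on input; they map to their parent level.
NODE_SUBLEVELS = {"IIa": "II", "IIb": "II", "Va": "V", "Vb": "V"}
LATERALITIES = ("left", "right")
LABELS = ("benign", "malignant")


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


@dataclass
class ImageVolume:
    """3D scalar grid with physical geometry.

    Parameters
    ----------
    values : (nx, ny, nz) float array, HU-like intensities.
    spacing : length-3 voxel spacing in mm (all > 0).
    origin : length-3 physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("ImageVolume.values must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive reals (mm)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RoiMask:
    """Binary region of interest aligned to an :class:`ImageVolume`.

    ``roi_type`` is ``"tumor"`` or ``"node"``; nodes carry ``level``
    (I--VI, sub-levels allowed), ``laterality`` and pathology ``label``.
    """

    mask: np.ndarray
    roi_type: str = "node"
    roi_id: str = ""
    level: Optional[str] = None
    laterality: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("RoiMask.mask must be 3D")
        if self.roi_type not in ("tumor", "node"):
            raise ValidationError(f"unknown roi_type {self.roi_type!r}")
        if not self.mask.any():
            raise ValidationError("RoiMask must contain at least one voxel")
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"unknown pathology label {self.label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PatientCase:
    """One patient: CT-like volume, tumor mask and contoured nodes."""

    patient_id: str
    tumor_type: str
    tumor_laterality: str  # "left" | "right" | "NA"
    volume: ImageVolume
    tumor_mask: RoiMask
    nodes: list[RoiMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tumor_type not in TUMOR_TYPES:
            raise ValidationError(f"unknown tumor_type {self.tumor_type!r}")
        if self.tumor_laterality not in ("left", "right", "NA"):
            raise ValidationError(
                f"unknown tumor_laterality {self.tumor_laterality!r}"
            )
        shape = self.volume.shape
        if self.tumor_mask.mask.shape != shape:
            raise ValidationError("tumor mask shape differs from volume shape")
        for node in self.nodes:
            if node.mask.shape != shape:
                raise ValidationError("node mask shape differs from volume shape")


def check_frames_match(a: ImageVolume, b: ImageVolume) -> None:
    if a.shape != b.shape or a.spacing != b.spacing:
        raise ValidationError("image frames differ (shape or spacing mismatch)")
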