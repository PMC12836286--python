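"""Lymphatic spatial/anatomical features.

Five features describe where a node sits relative to the primary tumor
and the lymphatic drainage map: integer codes for primary tumor type,
nodal level, node laterality and tumor laterality, plus the Euclidean
distance (mm) between the node and tumor mask centroids.

The integer encodings follow the standard clinical assignment used with
a Gaussian-kernel classifier (the nonlinear kernel treats them closer
to nominal categories than to an ordinal scale):

==================  =======================================  =====
Feature             Category                                 Code
==================  =======================================  =====
Primary tumor type  base of tongue                           1
                    tonsil                                   2
                    larynx                                   3
                    hypopharynx                              4
                    oropharynx                               5
Node level          I .. VI (IIa/IIb -> II, Va/Vb -> V)      1..6
Node laterality     left / right                             0 / 1
Tumor laterality    left / right / NA                        0 / 1 / 2
==================  =======================================  =====
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    NODE_SUBLEVELS,
    ImageVolume,
    PatientCase,
    RoiMask,
    ValidationError,
)

SPATIAL_FEATURE_NAMES = (
    "spatial_tumor_type_code",
    "spatial_node_level_code",
    "spatial_node_laterality_code",
    "spatial_tumor_laterality_code",
    "spatial_node_tumor_distance_mm",
)

TUMOR_TYPE_CODES = {
    "base_of_tongue": 1,
    "tonsil": 2,
    "larynx": 3,
    "hypopharynx": 4,
    "oropharynx": 5,
}
NODE_LEVEL_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}
NODE_LATERALITY_CODES = {"left": 0, "right": 1}
TUMOR_LATERALITY_CODES = {"left": 0, "right": 1, "NA": 2}

# Inverse maps for round-tripping codes back to categories.
TUMOR_TYPE_FROM_CODE = {v: k for k, v in TUMOR_TYPE_CODES.items()}
NODE_LEVEL_FROM_CODE = {v: k for k, v in NODE_LEVEL_CODES.items()}
NODE_LATERALITY_FROM_CODE = {v: k for k, v in NODE_LATERALITY_CODES.items()}
TUMOR_LATERALITY_FROM_CODE = {v: k for k, v in TUMOR_LATERALITY_CODES.items()}


@dataclass
class SpatialFeatures:
    tumor_type_code: int
    node_level_code: int
    node_laterality_code: int
    tumor_laterality_code: int
    node_tumor_distance_mm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "spatial_tumor_type_code": float(self.tumor_type_code),
            "spatial_node_level_code": float(self.node_level_code),
            "spatial_node_laterality_code": float(self.node_laterality_code),
            "spatial_tumor_laterality_code": float(self.tumor_laterality_code),
            "spatial_node_tumor_distance_mm": float(self.node_tumor_distance_mm),
        }


def encode_metadata(
    tumor_type: str, node_level: str, node_laterality: str, tumor_laterality: str
) -> tuple[int, int, int, int]:
    """Map the four categorical attributes to their integer codes.

    Node sub-levels (IIa, IIb, Va, Vb) map to their parent level code.
    Unknown categories raise :class:`ValidationError` naming the field.
    """
    if tumor_type not in TUMOR_TYPE_CODES:
        raise ValidationError(f"unknown tumor_type {tumor_type!r}")
    level = NODE_SUBLEVELS.get(node_level, node_level)
    if level not in NODE_LEVEL_CODES:
        raise ValidationError(f"unknown node_level {node_level!r}")
    if node_laterality not in NODE_LATERALITY_CODES:
        raise ValidationError(f"unknown node_laterality {node_laterality!r}")
    if tumor_laterality not in TUMOR_LATERALITY_CODES:
        raise ValidationError(f"unknown tumor_laterality {tumor_laterality!r}")
    return (
        TUMOR_TYPE_CODES[tumor_type],
        NODE_LEVEL_CODES[level],
        NODE_LATERALITY_CODES[node_laterality],
        TUMOR_LATERALITY_CODES[tumor_laterality],
    )


def centroid(roi: RoiMask, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Unweighted mean of in-mask voxel-center physical coordinates (mm)."""
    idx = np.argwhere(roi.mask)
    if idx.size == 0:
        raise ValidationError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    return idx.mean(axis=0) * spacing + origin


def node_tumor_distance(node: RoiMask, tumor: RoiMask, volume: ImageVolume) -> float:
    """Euclidean centroid-to-centroid distance (mm) in the volume's frame."""
    if node.mask.shape != volume.shape or tumor.mask.shape != volume.shape:
        raise ValidationError("mask frame differs from volume frame")
    c_node = centroid(node, volume.spacing, volume.origin)
    c_tumor = centroid(tumor, volume.spacing, volume.origin)
    return float(np.linalg.norm(c_node - c_tumor))


def extract_spatial(case: PatientCase, node_index: int) -> SpatialFeatures:
    """Assemble the five spatial features for one node of a patient."""
    if not 0 <= node_index < len(case.nodes):
        raise ValidationError(f"node index {node_index} out of range")
    node = case.nodes[node_index]
    if node.level is None or node.laterality is None:
        raise ValidationError("node is missing level or laterality metadata")
    codes = encode_metadata(
        case.tumor_type, node.level, node.laterality, case.tumor_laterality
    )
    dist = node_tumor_distance(node, case.tumor_mask, case.volume)
    return SpatialFeatures(*codes, dist)


def one_hot_spatial(features: SpatialFeatures) -> dict[str, float]:
    """Alternative one-hot expansion of the categorical codes.

    Provided as an opt-in encoding; the integer codes above are the
    default, tested path.
    """
    out: dict[str, float] = {}
    for name, code, n in (
        ("tumor_type", features.tumor_type_code, 5),
        ("node_level", features.node_level_code, 6),
    ):
        for k in range(1, n + 1):
            out[f"spatial_{name}_is_{k}"] = float(code == k)
    for name, code, n in (
        ("node_laterality", features.node_laterality_code, 2),
        ("tumor_laterality", features.tumor_laterality_code, 3),
    ):
        for k in range(n):
            out[f"spatial_{name}_is_{k}"] = float(code == k)
    out["spatial_node_tumor_distance_mm"] = features.node_tumor_distance_mm
    return out
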