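"""Shape descriptors of a binary ROI in physical (mm) units.

Seven features: volume, major and minor diameter, eccentricity,
elongation, axis-aligned bounding-box volume, and surface area measured
as the total area of exposed voxel faces.

Diameters derive from the principal axes of the voxel-center coordinate
cloud: with eigenvalues lam1 >= lam2 >= lam3 of the (population)
coordinate covariance in mm^2, the axis lengths are 4*sqrt(lam), the
convention under which a uniform segment of half-length L has axis
length ~ 4 * L / sqrt(12) * sqrt(3) (exact for continuous ellipsoids).
Degenerate single-voxel regions have zero-length axes and report
eccentricity 0.
"""

from __future__ import annotations

import numpy as np

from ..core import RoiMask, ValidationError

GEOMETRY_FEATURE_NAMES = (
    "geometry_volume_mm3",
    "geometry_major_diameter_mm",
    "geometry_minor_diameter_mm",
    "geometry_eccentricity",
    "geometry_elongation",
    "geometry_bbox_volume_mm3",
    "geometry_surface_area_mm2",
)


def geometry_features(roi: RoiMask, spacing) -> dict[str, float]:
    """Return the 7 geometry features of ``roi`` at voxel ``spacing`` (mm)."""
    mask = roi.mask
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValidationError("spacing must be three positive reals (mm)")
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValidationError("empty mask")
    n = idx.shape[0]
    voxel_volume = float(np.prod(spacing))

    coords = idx * spacing  # voxel-center physical coordinates
    cov = np.cov(coords, rowvar=False, bias=True) if n > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov)
    lam = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    major = 4.0 * np.sqrt(lam[0])
    minor = 4.0 * np.sqrt(lam[2])
    if lam[0] > 0:
        eccentricity = float(np.sqrt(1.0 - lam[2] / lam[0]))
        elongation = float(np.sqrt(lam[1] / lam[0]))
    else:
        eccentricity = 0.0
        elongation = 0.0

    extent = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing
    bbox_volume = float(np.prod(extent))

    return {
        "geometry_volume_mm3": n * voxel_volume,
        "geometry_major_diameter_mm": float(major),
        "geometry_minor_diameter_mm": float(minor),
        "geometry_eccentricity": eccentricity,
        "geometry_elongation": elongation,
        "geometry_bbox_volume_mm3": bbox_volume,
        "geometry_surface_area_mm2": _exposed_face_area(mask, spacing),
    }


def _exposed_face_area(mask: np.ndarray, spacing: np.ndarray) -> float:
    """Surface area (mm^2) as the sum of voxel faces not shared by the ROI."""
    face_areas = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    total = 0.0
    for axis, area in enumerate(face_areas):
        m = np.moveaxis(mask, axis, 0)
        interior = m[1:] & m[:-1]  # shared faces along this axis
        exposed = 2 * m.sum() - 2 * interior.sum()
        total += float(exposed) * area
    return total
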