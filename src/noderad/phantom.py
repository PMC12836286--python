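"""Synthetic neck phantoms: seeded cohorts of CT-like volumes and masks.

The generator emulates a head-and-neck cohort in a simplified neck
frame: a 96x96x96 voxel volume at 1 mm isotropic spacing, whose first
axis is left-right (midline at x = 48 mm), second axis
anterior-posterior and third axis superior-inferior.  A primary tumor
is placed at a site-specific canonical location; lymph nodes are
ellipsoids placed at level-specific canonical centers left/right of the
midline, jittered per node.

Malignancy is generated from a logistic model over six node attributes
-- distance to the tumor centroid, laterality concordance with the
tumor, nodal level, tumor type, node size and texture heterogeneity --
so that every spatial feature downstream carries signal by
construction.  Labels then feed back into rendering: malignant nodes
are drawn with larger axes and higher correlated-noise amplitude.

Cohort-level attribute sampling (:func:`sample_cohort_metadata`) is
separated from voxel rendering (:func:`render_patient`,
:func:`generate_cohort`) so statistical checks on the generative model
can run on thousands of nodes without touching image data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ImageVolume, PatientCase, RoiMask, TUMOR_TYPES, ValidationError

__all__ = [
    "PhantomConfig",
    "NodeMeta",
    "PatientMeta",
    "sample_cohort_metadata",
    "malignancy_probability",
    "render_patient",
    "generate_cohort",
    "iter_cohort",
]

# Canonical tumor site centers (x, y, z) in mm within the 96 mm frame;
# lateralized sites are offset from the midline along +-x.
_SITE_CENTERS = {
    "base_of_tongue": ((48.0, 40.0, 28.0), 6.0),
    "tonsil": ((48.0, 44.0, 26.0), 14.0),
    "oropharynx": ((48.0, 42.0, 30.0), 8.0),
    "larynx": ((48.0, 46.0, 58.0), 4.0),
    "hypopharynx": ((48.0, 52.0, 60.0), 4.0),
}

# Level-specific canonical node centers: (|x offset from midline|, y, z).
_LEVEL_CENTERS = {
    "I": (12.0, 30.0, 30.0),
    "II": (20.0, 42.0, 30.0),
    "III": (20.0, 44.0, 46.0),
    "IV": (18.0, 46.0, 62.0),
    "V": (30.0, 54.0, 44.0),
    "VI": (6.0, 38.0, 66.0),
}
_LEVELS = tuple(_LEVEL_CENTERS)
_LEVEL_PROBS = (0.10, 0.30, 0.25, 0.15, 0.12, 0.08)

# Fixed per-level and per-site contributions to the malignancy logit,
# scaled by the level-affinity weight.  Levels II/III drain most
# primary sites and are made the most metastasis-prone.
_LEVEL_AFFINITY = {"I": -0.3, "II": 0.7, "III": 0.4, "IV": -0.1, "V": -0.5, "VI": -0.6}
_TYPE_EFFECT = {
    "base_of_tongue": 0.25,
    "tonsil": 0.10,
    "oropharynx": 0.0,
    "larynx": -0.15,
    "hypopharynx": 0.0,
}

# Fraction of level II / V nodes reported with a clinical sub-level.
_SUBLEVEL_PROB = 0.3

_MIDLINE = 48.0


@dataclass
class PhantomConfig:
    """Stated world of the synthetic cohort.

    Defaults emulate the clinical cohort the pipeline is aimed at:
    192 patients, site mix 34/32/3/28/3 % (base of tongue, tonsil,
    oropharynx, larynx, hypopharynx), ~7.2 nodes per patient and an
    overall malignant fraction near 270/1389 ~ 0.194.

    ``malignancy_logit_weights`` is the 6-vector (intercept, distance
    [per mm], laterality concordance, level affinity scale, size
    [per 1000 mm^3], heterogeneity [per relative noise-sd excess]).
    """

    n_patients: int = 192
    site_probs: tuple[float, ...] = (0.34, 0.32, 0.03, 0.28, 0.03)
    mean_nodes_per_patient: float = 7.2
    malignancy_logit_weights: tuple[float, ...] = (
        -1.38,  # intercept, calibrated to the target prevalence 270/1389
        -0.06,
        1.4,
        1.0,
        0.6,
        1.0,
    )
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    volume_shape: tuple[int, int, int] = (96, 96, 96)
    noise_sd_benign: float = 8.0
    noise_sd_malignant: float = 14.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        probs = np.asarray(self.site_probs, dtype=float)
        if probs.shape != (5,) or np.any(probs < 0):
            raise ValidationError("site_probs must be 5 nonnegative reals")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("site_probs must sum to 1")
        if self.mean_nodes_per_patient <= 0:
            raise ValidationError("mean_nodes_per_patient must be > 0")
        if self.noise_sd_benign <= 0 or self.noise_sd_malignant <= 0:
            raise ValidationError("noise sds must be > 0")
        if len(self.malignancy_logit_weights) != 6:
            raise ValidationError("malignancy_logit_weights must have 6 entries")
        if not np.all(np.isfinite(self.malignancy_logit_weights)):
            raise ValidationError("malignancy_logit_weights must be finite")


@dataclass
class NodeMeta:
    node_id: str
    level: str  # reported level, may be a sub-level (IIa, Vb, ...)
    parent_level: str
    laterality: str
    center: np.ndarray  # mm
    semi_axes: np.ndarray  # mm, after any malignant enlargement
    size_mm3: float  # pre-render ellipsoid volume entering the logit
    heterogeneity_sd: float  # latent noise sd (HU) entering the logit
    render_noise_sd: float
    distance_mm: float
    laterality_concordant: bool
    p_malignant: float
    label: str


@dataclass
class PatientMeta:
    patient_id: str
    tumor_type: str
    tumor_laterality: str
    tumor_center: np.ndarray
    tumor_semi_axes: np.ndarray
    nodes: list[NodeMeta] = field(default_factory=list)


def malignancy_probability(
    config: PhantomConfig,
    distance_mm: float,
    laterality_concordant: bool,
    level: str,
    tumor_type: str,
    size_mm3: float,
    heterogeneity_sd: float,
) -> float:
    """Logistic malignancy probability of a node given its attributes.

    Strictly decreasing in distance for a negative distance weight;
    always in (0, 1).
    """
    w0, w_d, w_c, w_a, w_s, w_h = config.malignancy_logit_weights
    from .core import NODE_SUBLEVELS

    parent = NODE_SUBLEVELS.get(level, level)
    if parent not in _LEVEL_AFFINITY:
        raise ValidationError(f"unknown node level {level!r}")
    if tumor_type not in _TYPE_EFFECT:
        raise ValidationError(f"unknown tumor_type {tumor_type!r}")
    logit = (
        w0
        + w_d * float(distance_mm)
        + w_c * float(bool(laterality_concordant))
        + w_a * _LEVEL_AFFINITY[parent]
        + w_s * float(size_mm3) / 1000.0
        + w_h * (float(heterogeneity_sd) / config.noise_sd_benign - 1.0)
        + _TYPE_EFFECT[tumor_type]
    )
    return 1.0 / (1.0 + math.exp(-logit))


def _sample_patient_meta(
    config: PhantomConfig, rng: np.random.Generator, index: int
) -> PatientMeta:
    shape_mm = np.asarray(config.volume_shape) * np.asarray(config.voxel_spacing)
    scale = shape_mm / 96.0  # canonical frame is 96 mm

    tumor_type = TUMOR_TYPES[rng.choice(5, p=np.asarray(config.site_probs))]
    if tumor_type == "oropharynx" and rng.random() < 0.5:
        tumor_laterality = "NA"
    else:
        tumor_laterality = "left" if rng.random() < 0.5 else "right"
    (cx, cy, cz), lat_offset = _SITE_CENTERS[tumor_type]
    if tumor_laterality == "left":
        cx -= lat_offset
    elif tumor_laterality == "right":
        cx += lat_offset
    tumor_center = (np.array([cx, cy, cz]) + rng.normal(0, 2.0, 3)) * scale
    tumor_axes = rng.uniform(8.0, 14.0, 3) * scale

    meta = PatientMeta(
        patient_id=f"P{index:04d}",
        tumor_type=tumor_type,
        tumor_laterality=tumor_laterality,
        tumor_center=tumor_center,
        tumor_semi_axes=tumor_axes,
    )

    n_nodes = max(1, int(rng.poisson(config.mean_nodes_per_patient)))
    for k in range(n_nodes):
        parent = _LEVELS[rng.choice(6, p=_LEVEL_PROBS)]
        level = parent
        if parent in ("II", "V") and rng.random() < _SUBLEVEL_PROB:
            level = parent + ("a" if rng.random() < 0.5 else "b")
        side = "left" if rng.random() < 0.5 else "right"
        off, ny, nz = _LEVEL_CENTERS[parent]
        nx = _MIDLINE - off if side == "left" else _MIDLINE + off
        center = (np.array([nx, ny, nz]) + rng.normal(0, 2.5, 3)) * scale

        base_axis = rng.lognormal(math.log(4.0), 0.25)
        axes = base_axis * rng.uniform(0.8, 1.25, 3)
        size_mm3 = 4.0 / 3.0 * math.pi * float(np.prod(axes))
        het_mult = rng.lognormal(0.0, 0.35)
        het_sd = config.noise_sd_benign * het_mult

        distance = float(np.linalg.norm(center - tumor_center))
        concordant = tumor_laterality == side
        p = malignancy_probability(
            config, distance, concordant, level, tumor_type, size_mm3, het_sd
        )
        malignant = rng.random() < p
        if malignant:
            axes = axes * 1.25  # malignant nodes rendered larger
            render_sd = config.noise_sd_malignant * het_mult
        else:
            render_sd = config.noise_sd_benign * het_mult

        meta.nodes.append(
            NodeMeta(
                node_id=f"{meta.patient_id}_n{k:02d}",
                level=level,
                parent_level=parent,
                laterality=side,
                center=center,
                semi_axes=axes,
                size_mm3=size_mm3,
                heterogeneity_sd=het_sd,
                render_noise_sd=render_sd,
                distance_mm=distance,
                laterality_concordant=concordant,
                p_malignant=p,
                label="malignant" if malignant else "benign",
            )
        )
    return meta


def sample_cohort_metadata(config: PhantomConfig) -> list[PatientMeta]:
    """Sample all patient/node attributes and labels without rendering.

    Deterministic for a fixed ``config.seed``; the rendering path draws
    from an independent sub-stream so metadata are identical whether or
    not volumes are rendered.
    """
    config.validate()
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    return [_sample_patient_meta(config, rng, i) for i in range(config.n_patients)]


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    center: np.ndarray,
    semi_axes: np.ndarray,
) -> np.ndarray:
    lo = np.maximum(np.floor((center - semi_axes) / spacing).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil((center + semi_axes) / spacing).astype(int) + 2, np.asarray(shape)
    )
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    grids = np.meshgrid(
        *(np.arange(a, b) * s for a, b, s in zip(lo, hi, spacing)), indexing="ij"
    )
    r2 = sum(((g - c) / ax) ** 2 for g, c, ax in zip(grids, center, semi_axes))
    mask[tuple(slice(a, b) for a, b in zip(lo, hi))] = r2 <= 1.0
    return mask


def _correlated_noise(
    rng: np.random.Generator, mask: np.ndarray, sd: float
) -> np.ndarray:
    """White noise smoothed with a Gaussian kernel, rescaled to sd (in-mask)."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - 3, 0)
    hi = np.minimum(idx.max(axis=0) + 4, np.asarray(mask.shape))
    crop = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    white = rng.standard_normal([int(b - a) for a, b in zip(lo, hi)])
    smooth = gaussian_filter(white, sigma=1.2)
    m = mask[crop]
    s = smooth[m].std()
    out = np.zeros(mask.shape)
    out[crop][m] = smooth[m] / s * sd if s > 0 else 0.0
    return out


def render_patient(config: PhantomConfig, meta: PatientMeta) -> PatientCase:
    """Render one patient's volume and disjoint tumor/node masks.

    The render RNG is seeded from ``config.seed`` and the patient index
    so individual patients can be re-rendered independently.
    """
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    shape = tuple(config.volume_shape)
    pidx = int(meta.patient_id[1:])
    rng = np.random.default_rng(np.random.PCG64((config.seed, 1, pidx)))

    values = 40.0 + rng.normal(0.0, 2.0, shape)  # soft-tissue background
    occupied = np.zeros(shape, dtype=bool)

    tumor = _ellipsoid_mask(shape, spacing, meta.tumor_center, meta.tumor_semi_axes)
    if not tumor.any():  # degenerate placement; fall back to one voxel
        tumor[tuple(np.clip((meta.tumor_center / spacing).astype(int), 0, np.array(shape) - 1))] = True
    values[tumor] = 65.0
    values += _correlated_noise(rng, tumor, 10.0)
    occupied |= tumor

    volume_mm = np.asarray(shape) * spacing
    node_masks: list[RoiMask] = []
    kept_nodes: list[NodeMeta] = []
    for node in meta.nodes:
        center = np.clip(node.center, node.semi_axes + 1.0, volume_mm - node.semi_axes - 1.0)
        mask = None
        for _ in range(30):
            m = _ellipsoid_mask(shape, spacing, center, node.semi_axes)
            if m.any() and not (m & occupied).any():
                mask = m
                break
            center = np.clip(
                node.center + rng.normal(0, 2.0, 3),
                node.semi_axes + 1.0,
                volume_mm - node.semi_axes - 1.0,
            )
        if mask is None:  # carve out any residual overlap
            mask = _ellipsoid_mask(shape, spacing, center, node.semi_axes) & ~occupied
            if not mask.any():
                continue  # unplaceable node dropped (rare, logged upstream)
        values[mask] = 55.0
        values += _correlated_noise(rng, mask, node.render_noise_sd)
        occupied |= mask
        node_masks.append(
            RoiMask(
                mask=mask,
                roi_type="node",
                roi_id=node.node_id,
                level=node.level,
                laterality=node.laterality,
                label=node.label,
            )
        )
        kept_nodes.append(node)
    meta.nodes = kept_nodes

    return PatientCase(
        patient_id=meta.patient_id,
        tumor_type=meta.tumor_type,
        tumor_laterality=meta.tumor_laterality,
        volume=ImageVolume(values, tuple(spacing), (0.0, 0.0, 0.0)),
        tumor_mask=RoiMask(mask=tumor, roi_type="tumor", roi_id=f"{meta.patient_id}_tumor"),
        nodes=node_masks,
    )


def iter_cohort(config: PhantomConfig):
    """Yield ``(PatientMeta, PatientCase)`` pairs one patient at a time.

    Streaming form of :func:`generate_cohort`: volumes are rendered
    lazily so a full cohort never has to reside in memory at once.
    """
    for meta in sample_cohort_metadata(config):
        yield meta, render_patient(config, meta)


def generate_cohort(config: PhantomConfig) -> list[PatientCase]:
    """Generate the full cohort in memory (small cohorts only)."""
    return [case for _, case in iter_cohort(config)]
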