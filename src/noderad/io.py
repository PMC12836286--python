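"""Disk formats: NIfTI volumes/masks, cohort metadata CSV, JSON manifest.

Cohort layout on disk::

    cohort_dir/
      manifest.json           # patient ids, file paths, generator config
      metadata.csv            # one row per ROI (tumor + nodes)
      P0000/volume.nii.gz
      P0000/tumor.nii.gz
      P0000/node_00.nii.gz ...

The metadata CSV schema is ``patient_id, roi_id, roi_type, tumor_type,
level, laterality, label``; user-supplied cohorts with the same layout
can be read back with :func:`read_cohort`.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ImageVolume, PatientCase, RoiMask, ValidationError

METADATA_COLUMNS = (
    "patient_id",
    "roi_id",
    "roi_type",
    "tumor_type",
    "level",
    "laterality",
    "label",
)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _save_nifti(path: Path, data: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing))
    nib.save(img, str(path))


def write_patient(case: PatientCase, cohort_dir: Path) -> list[dict]:
    """Write one patient's NIfTI files; return metadata rows."""
    pdir = Path(cohort_dir) / case.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    spacing = case.volume.spacing
    _save_nifti(pdir / "volume.nii.gz", case.volume.values.astype(np.float32), spacing)
    _save_nifti(pdir / "tumor.nii.gz", case.tumor_mask.mask.astype(np.uint8), spacing)
    rows = [
        {
            "patient_id": case.patient_id,
            "roi_id": case.tumor_mask.roi_id or f"{case.patient_id}_tumor",
            "roi_type": "tumor",
            "tumor_type": case.tumor_type,
            "level": "",
            "laterality": case.tumor_laterality,
            "label": "",
        }
    ]
    for i, node in enumerate(case.nodes):
        _save_nifti(pdir / f"node_{i:02d}.nii.gz", node.mask.astype(np.uint8), spacing)
        rows.append(
            {
                "patient_id": case.patient_id,
                "roi_id": node.roi_id or f"{case.patient_id}_n{i:02d}",
                "roi_type": "node",
                "tumor_type": case.tumor_type,
                "level": node.level,
                "laterality": node.laterality,
                "label": node.label,
            }
        )
    return rows


def write_cohort(cases, cohort_dir, config_dict: dict | None = None) -> Path:
    """Write a cohort (iterable of PatientCase) to ``cohort_dir``."""
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    patient_ids: list[str] = []
    for case in cases:
        rows.extend(write_patient(case, cohort_dir))
        patient_ids.append(case.patient_id)
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        cohort_dir / "metadata.csv", index=False
    )
    manifest = {
        "format_version": 1,
        "n_patients": len(patient_ids),
        "patient_ids": patient_ids,
        "config": config_dict or {},
    }
    (cohort_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cohort_dir


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def read_patient(cohort_dir: Path, patient_id: str, meta: pd.DataFrame) -> PatientCase:
    pdir = Path(cohort_dir) / patient_id
    values, spacing = _load_nifti(pdir / "volume.nii.gz")
    volume = ImageVolume(values, spacing)
    tumor_data, _ = _load_nifti(pdir / "tumor.nii.gz")
    rows = meta[meta["patient_id"] == patient_id]
    trow = rows[rows["roi_type"] == "tumor"]
    if len(trow) != 1:
        raise ValidationError(f"{patient_id}: expected exactly one tumor row")
    trow = trow.iloc[0]
    tumor = RoiMask(tumor_data > 0, roi_type="tumor", roi_id=str(trow["roi_id"]))
    nodes = []
    node_rows = rows[rows["roi_type"] == "node"].reset_index(drop=True)
    for i, row in node_rows.iterrows():
        data, _ = _load_nifti(pdir / f"node_{i:02d}.nii.gz")
        nodes.append(
            RoiMask(
                data > 0,
                roi_type="node",
                roi_id=str(row["roi_id"]),
                level=str(row["level"]),
                laterality=str(row["laterality"]),
                label=str(row["label"]),
            )
        )
    return PatientCase(
        patient_id=patient_id,
        tumor_type=str(trow["tumor_type"]),
        tumor_laterality=str(trow["laterality"]),
        volume=volume,
        tumor_mask=tumor,
        nodes=nodes,
    )


def read_cohort(cohort_dir):
    """Yield PatientCase objects from a cohort directory, one at a time."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    meta = pd.read_csv(cohort_dir / "metadata.csv", keep_default_na=False)
    for pid in manifest["patient_ids"]:
        yield read_patient(cohort_dir, pid, meta)
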