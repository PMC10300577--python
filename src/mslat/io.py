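"""NIfTI and table I/O for visit bundles, maps and transforms."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import SubjectTimepoint

VISIT_FILES = {
    "pd_img": "pd.nii.gz",
    "t1_img": "t1.nii.gz",
    "brain_mask": "brain_mask.nii.gz",
    "lesion_mask": "lesion_mask.nii.gz",
    "ventricle_mask": "ventricle_mask.nii.gz",
}


def save_nifti(data: np.ndarray, spacing, path) -> None:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.asarray(data), aff), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_visit(visit: SubjectTimepoint, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for attr, fname in VISIT_FILES.items():
        save_nifti(getattr(visit, attr), visit.spacing, d / fname)


def load_visit(directory) -> SubjectTimepoint:
    d = Path(directory)
    arrays = {}
    spacing = None
    for attr, fname in VISIT_FILES.items():
        data, spacing = load_nifti(d / fname)
        if attr.endswith("mask"):
            data = data.astype(bool)
        else:
            data = data.astype(np.float64)
        arrays[attr] = data
    return SubjectTimepoint(spacing_mm=spacing, **arrays)


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic CSV output (fixed float formatting, no index)."""
    df.to_csv(path, index=False, float_format="%.10g")
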