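"""File formats: NIfTI volumes and masks, cohort CSV, JSON records.

Volumes travel as NIfTI-1 with the voxel dimensions in the header zooms
(affine = diag(voxel dims)); BVF maps are float32 in [0, 1] and masks
uint8 over {0, 1, 2}.  Tables are UTF-8 CSV with a header row and '.'
decimals.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bvf import BVFMap, GrayscaleVolume, SegmentationMask
from .cohort import COHORT_COLUMNS

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_bvf", "write_bvf", "read_cohort_csv", "write_cohort_csv",
    "write_json_atomic", "write_csv_atomic",
]


def _load_nifti(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as err:  # malformed header / not NIfTI
        raise ValueError(f"cannot read {path} as NIfTI-1: {err}") from err
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: header field 'pixdim' has non-positive zooms")
    return data, tuple(float(z) for z in zooms)


def _save_nifti(data: np.ndarray, voxel_dims, path: str | Path,
                dtype) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_dims) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(voxel_dims)
    fd, tmp = tempfile.mkstemp(suffix=".nii", dir=path.parent)
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def read_volume(path: str | Path) -> GrayscaleVolume:
    data, zooms = _load_nifti(path)
    return GrayscaleVolume(np.asarray(data, dtype=np.float64), zooms)


def write_volume(volume: GrayscaleVolume, path: str | Path) -> None:
    _save_nifti(volume.data, volume.voxel_dims, path, np.float32)


def read_mask(path: str | Path) -> SegmentationMask:
    data, zooms = _load_nifti(path)
    return SegmentationMask(data, zooms)   # label validation in the type


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    _save_nifti(mask.labels, mask.voxel_dims, path, np.uint8)


def read_bvf(path: str | Path) -> BVFMap:
    data, zooms = _load_nifti(path)
    return BVFMap(np.asarray(data, dtype=np.float64), zooms)


def write_bvf(bvf: BVFMap, path: str | Path) -> None:
    _save_nifti(bvf.bvf, bvf.voxel_dims, path, np.float32)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    write_csv_atomic(df, path)


def write_csv_atomic(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(suffix=".csv", dir=path.parent)
    os.close(fd)
    try:
        df.to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_json_atomic(payload, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(suffix=".json", dir=path.parent)
    os.close(fd)
    try:
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonify)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
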