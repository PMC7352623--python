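"""File formats: NIfTI volumes/series, TIFF sections, CSV tables, JSON models."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = ["save_nifti", "load_nifti", "save_tiff", "load_tiff",
           "save_json", "load_json", "file_sha256"]


def save_nifti(path, array: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    """Write a volume or 4-D series (4th axis = b/TI/time) as NIfTI."""
    path = Path(path)
    affine = np.diag(list(voxel_size_mm[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    img.header.set_zooms(tuple(voxel_size_mm[:3]) + ((1.0,) if array.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def save_tiff(path, array: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(array))
    return path


def load_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))
    return path


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
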