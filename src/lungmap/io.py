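"""NIfTI read/write helpers (time as the third axis for series)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti"]


def save_nifti(array: np.ndarray, path, voxel_size_mm: float = 6.25,
               slice_thickness_mm: float = 15.0) -> Path:
    """Write a 2D map or a (time, H, W) series as NIfTI.

    Series are stored with time as the third axis, matching how a 2D+time
    stack is conventionally packed into a single-slice volume.
    """
    array = np.asarray(array)
    if array.ndim == 3:            # (t, H, W) -> (H, W, t)
        data = np.moveaxis(array, 0, -1)
        zooms = (voxel_size_mm, voxel_size_mm, 1.0)
    elif array.ndim == 2:
        data = array
        zooms = (voxel_size_mm, voxel_size_mm)
    else:
        raise ValueError("expected a 2D map or a (time, H, W) series")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))
    img.header.set_zooms(zooms)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_nifti(path, series: bool = False) -> np.ndarray:
    """Read a NIfTI map; with ``series=True`` return a (time, H, W) stack."""
    data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if series:
        if data.ndim != 3:
            raise ValueError(f"{path} is not a 2D+time series")
        return np.moveaxis(data, -1, 0)
    return data
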