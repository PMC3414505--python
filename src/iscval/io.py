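"""NIfTI and three-column event file I/O."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_three_column",
    "read_three_column",
    "load_cohort_data",
]


def write_nifti(path, data: np.ndarray, voxel_size: float, tr: float | None = None) -> None:
    """Write a 3-D/4-D grid with an isotropic diagonal affine.

    For 4-D data the repetition time is stored in the header zooms.
    """
    data = np.asarray(data)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(data, affine)
    if data.ndim == 4 and tr is not None:
        img.header.set_zooms((voxel_size,) * 3 + (float(tr),))
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, float, float | None]:
    """Read a NIfTI file; returns (data, voxel_size, tr-or-None)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else None
    return data, float(zooms[0]), tr


def write_three_column(path, events: np.ndarray) -> None:
    """Write an FSL-style three-column event file (onset, duration, value)."""
    events = np.asarray(events, dtype=float)
    if events.ndim != 2 or events.shape[1] != 3:
        raise ValueError("events must be an (n, 3) array")
    np.savetxt(str(path), events, fmt="%.6g")


def read_three_column(path) -> np.ndarray:
    events = np.loadtxt(str(path), ndmin=2)
    if events.shape[1] != 3:
        raise ValueError(f"{path}: expected three columns")
    return events


def load_cohort_data(paths: Sequence, expect_tr: float | None = None) -> tuple[np.ndarray, float, float]:
    """Stack per-subject 4-D files into (n_subjects, x, y, z, t).

    All subjects must share grid dimensions and TR; mismatches raise with
    the offending file named.
    """
    if len(paths) < 2:
        raise ValueError("a cohort needs at least two subjects")
    volumes = []
    ref_shape = None
    ref_vox = None
    ref_tr = expect_tr
    for p in paths:
        data, vox, tr = read_nifti(p)
        if data.ndim != 4:
            raise ValueError(f"{p}: expected a 4-D volume")
        if ref_shape is None:
            ref_shape, ref_vox = data.shape, vox
            if ref_tr is None:
                ref_tr = tr
        if data.shape != ref_shape:
            raise ValueError(
                f"{p}: shape {data.shape} does not match cohort shape {ref_shape}"
            )
        if tr is not None and ref_tr is not None and not np.isclose(tr, ref_tr):
            raise ValueError(f"{p}: TR {tr} does not match cohort TR {ref_tr}")
        volumes.append(data)
    return np.stack(volumes), float(ref_vox), float(ref_tr) if ref_tr else 0.0


def _ensure_dir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
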