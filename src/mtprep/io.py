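"""File formats: HDF5 raw-data container and NIfTI volumes.

The raw container stores the segmented acquisition compactly (acquired
profiles only):

    /kspace    complex (n_coil, n_beat, profiles, n_read)
    /indices   int     (n_beat, profiles, 2)   phase-encode (line, partition)
    /coils     complex (n_coil, nx, ny, nz)
    /trace     float   (2, n_beat)             (d_LR, d_FH) mm
    attrs: shape, voxel_size_mm, heart_rate_bpm

Volumes, masks and label maps go through NIfTI-1 with an RAS affine built
from the voxel size (mm).
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .recon import CartesianKSpace, DisplacementTrace

__all__ = [
    "save_raw",
    "load_raw",
    "save_nifti",
    "load_nifti",
    "save_json_report",
]


def save_raw(
    path,
    ksp: CartesianKSpace,
    coils: np.ndarray | None = None,
    trace: DisplacementTrace | None = None,
    heart_rate: float | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ksp.data)
        f.create_dataset("indices", data=ksp.indices)
        if coils is not None:
            f.create_dataset("coils", data=coils)
        if trace is not None:
            f.create_dataset("trace", data=np.stack([trace.d_lr, trace.d_fh]))
        f.attrs["shape"] = ksp.shape
        f.attrs["voxel_size_mm"] = ksp.voxel_size
        if heart_rate is not None:
            f.attrs["heart_rate_bpm"] = heart_rate


def load_raw(path):
    """Returns (CartesianKSpace, coils or None, DisplacementTrace or None)."""
    with h5py.File(path, "r") as f:
        ksp = CartesianKSpace(
            data=f["kspace"][()],
            indices=f["indices"][()],
            shape=tuple(int(v) for v in f.attrs["shape"]),
            voxel_size=tuple(float(v) for v in f.attrs["voxel_size_mm"]),
        )
        coils = f["coils"][()] if "coils" in f else None
        trace = None
        if "trace" in f:
            t = f["trace"][()]
            trace = DisplacementTrace(t[0], t[1])
    return ksp, coils, trace


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_nifti(path, volume: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    elif np.iscomplexobj(vol):
        vol = np.abs(vol)
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size)), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel


def save_json_report(path, report: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as f:
        json.dump(report, f, indent=2, default=default)
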