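"""Raw-data container (HDF5), trajectory export, and NIfTI image I/O.

The raw container is self-describing: complex multi-coil samples, the full
trajectory, the shot schedule, and provenance metadata (software version,
seed, configuration hash) live in one file.  Images are written as NIfTI
with an RAS+ affine built from the FOV and matrix (axial slices along the
third axis).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from . import __version__
from .phantom import KSpaceDataSet
from .recon import ImageSeries, ImageVolume
from .trajectory import StackOfSpiralsTrajectory

__all__ = [
    "write_raw", "read_raw",
    "save_nifti", "load_nifti",
    "export_trajectory", "import_trajectory",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_raw(data: KSpaceDataSet, path, extra_meta: dict | None = None
              ) -> None:
    """Write a KSpaceDataSet to the repository HDF5 layout."""
    traj = data.trajectory
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data.data.astype(np.complex128))
        g = f.create_group("trajectory")
        g.create_dataset("kx", data=traj.kx)
        g.create_dataset("ky", data=traj.ky)
        g.create_dataset("kz", data=traj.kz)
        g.attrs["slice_encode_order"] = traj.slice_encode_order
        s = f.create_group("schedule")
        s.create_dataset("tags", data=np.array(data.tags, dtype="S8"))
        s.create_dataset("interleaves", data=data.interleaves)
        m = f.attrs
        m["fov"] = traj.fov
        m["matrix"] = traj.matrix
        m["dwell"] = traj.dwell
        m["increment"] = traj.increment
        m["version"] = __version__
        for k, v in {**data.meta, **(extra_meta or {})}.items():
            if v is not None:
                m[str(k)] = v


def read_raw(path) -> KSpaceDataSet:
    """Read the repository HDF5 layout back into a KSpaceDataSet."""
    with h5py.File(path, "r") as f:
        if "trajectory" not in f:
            raise ValueError("corrupt raw file: missing /trajectory")
        if "data" not in f:
            raise ValueError("corrupt raw file: missing /data")
        g = f["trajectory"]
        traj = StackOfSpiralsTrajectory(
            kx=g["kx"][()], ky=g["ky"][()], kz=g["kz"][()],
            slice_encode_order=np.asarray(g.attrs["slice_encode_order"]),
            fov=tuple(f.attrs["fov"]),
            matrix=tuple(int(n) for n in f.attrs["matrix"]),
            dwell=float(f.attrs["dwell"]),
            increment=float(f.attrs["increment"]),
        )
        meta = {k: f.attrs[k] for k in f.attrs
                if k not in ("fov", "matrix", "dwell", "increment")}
        return KSpaceDataSet(
            data=f["data"][()],
            trajectory=traj,
            tags=[t.decode() for t in f["schedule/tags"][()]],
            interleaves=f["schedule/interleaves"][()],
            meta=meta,
        )


def export_trajectory(traj: StackOfSpiralsTrajectory, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("kx", "ky", "kz"):
            f.create_dataset(name, data=getattr(traj, name))
        f.attrs["fov"] = traj.fov
        f.attrs["matrix"] = traj.matrix
        f.attrs["dwell"] = traj.dwell
        f.attrs["increment"] = traj.increment
        f.attrs["slice_encode_order"] = traj.slice_encode_order
        f.attrs["version"] = __version__


def import_trajectory(path) -> StackOfSpiralsTrajectory:
    with h5py.File(path, "r") as f:
        return StackOfSpiralsTrajectory(
            kx=f["kx"][()], ky=f["ky"][()], kz=f["kz"][()],
            slice_encode_order=np.asarray(f.attrs["slice_encode_order"]),
            fov=tuple(f.attrs["fov"]),
            matrix=tuple(int(n) for n in f.attrs["matrix"]),
            dwell=float(f.attrs["dwell"]),
            increment=float(f.attrs["increment"]),
        )


def save_nifti(volume, path, voxel_size_mm=None) -> None:
    """Save an ImageVolume / ImageSeries / bare array as NIfTI (RAS+)."""
    if isinstance(volume, ImageVolume):
        arr, vs = np.abs(volume.data), volume.voxel_size
    elif isinstance(volume, ImageSeries):
        arr = np.moveaxis(np.abs(volume.volumes), 0, -1)  # x,y,z,t
        vs = volume.voxel_size
    else:
        arr = np.asarray(volume)
        vs = voxel_size_mm or (1.0, 1.0, 1.0)
    img = nib.Nifti1Image(arr.astype(np.float32), _affine(vs))
    img.header.set_zooms(tuple(vs) + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path):
    """Load a NIfTI file -> (array, voxel_size_mm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), tuple(float(z) for z in zooms)
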