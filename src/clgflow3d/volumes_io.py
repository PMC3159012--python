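"""I/O and grid conventions for 3D volumes and dense displacement fields.

Arrays are indexed ``(x, y, z)``: axis 0 is x, and x is the fastest-varying
index in the on-disk layout (Fortran order for raw binary, which is also the
native NIfTI layout).  Voxel ``(i, j, k)`` sits at continuous coordinate
``(i*h, j*h, k*h)`` where ``h`` is the isotropic voxel edge length.
Displacement fields are stored and manipulated in voxel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "MotionField",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
]

_SPACING_RTOL = 1e-6


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with isotropic voxel spacing ``h``."""

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D data: got {self.data.ndim} dimensions")
        if min(self.data.shape) < 2:
            raise ValueError("each axis needs at least 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if not (self.spacing > 0):
            raise ValueError("spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class MotionField:
    """Per-voxel displacement ``(u, v, w)`` along x, y, z, in voxel units."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if not (self.u.shape == self.v.shape == self.w.shape):
            raise ValueError("component shape mismatch")
        if self.u.ndim != 3:
            raise ValueError("motion components must be 3D")
        for c in (self.u, self.v, self.w):
            if not np.all(np.isfinite(c)):
                raise ValueError("displacements must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.u.shape

    @classmethod
    def zeros(cls, dims: tuple[int, int, int]) -> "MotionField":
        return cls(np.zeros(dims), np.zeros(dims), np.zeros(dims))

    def as_array(self) -> np.ndarray:
        """Stack to a 4D array with last axis (u, v, w)."""
        return np.stack([self.u, self.v, self.w], axis=-1)

    def copy(self) -> "MotionField":
        return MotionField(self.u.copy(), self.v.copy(), self.w.copy())


def _check_isotropic(zooms) -> float:
    zooms = np.asarray(zooms[:3], dtype=float)
    if np.any(zooms <= 0):
        # absent/zero pixdim: fall back to unit spacing
        return 1.0
    ref = zooms[0]
    if np.any(np.abs(zooms - ref) > _SPACING_RTOL * ref):
        raise ValueError(f"anisotropic spacing {tuple(zooms)} not supported")
    return float(ref)


def read_volume(path) -> VolumeImage:
    """Read a 3D volume from NIfTI (.nii/.nii.gz) or raw binary + JSON sidecar.

    Raw files hold little-endian float32 in x-fastest order; the sidecar
    ``<path>.json`` carries ``{"dims": [Nx, Ny, Nz], "dtype", "spacing"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"non-3D data: shape {data.shape}")
        h = _check_isotropic(img.header.get_zooms())
        return VolumeImage(np.asarray(data, dtype=np.float64), spacing=h)
    if path.suffix == ".raw":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        dims = tuple(int(d) for d in meta["dims"])
        if len(dims) != 3:
            raise ValueError("non-3D data in sidecar dims")
        dtype = np.dtype(meta.get("dtype", "<f4"))
        raw = np.fromfile(path, dtype=dtype)
        if raw.size != int(np.prod(dims)):
            raise ValueError(
                f"raw file has {raw.size} values, dims {dims} need {int(np.prod(dims))}"
            )
        data = raw.reshape(dims, order="F")  # x fastest
        spacing = meta.get("spacing", 1.0)
        if np.ndim(spacing) > 0:
            spacing = _check_isotropic(list(spacing) + [spacing[0]] * (3 - len(spacing)))
        return VolumeImage(data.astype(np.float64), spacing=float(spacing))
    raise ValueError(f"unsupported format: {path.name}")


def _nifti_header(descrip: str) -> nib.Nifti1Header:
    hdr = nib.Nifti1Header()
    hdr["descrip"] = descrip.encode()[:79]
    return hdr


def write_volume(vol: VolumeImage, path) -> None:
    """Write a volume readable back by :func:`read_volume` (NIfTI or raw)."""
    path = Path(path)
    if path.suffix == ".raw":
        vol.data.astype("<f4").ravel(order="F").tofile(path)  # x fastest on disk
        sidecar = {"dims": list(vol.dims), "dtype": "<f4", "spacing": vol.spacing}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
        return
    hdr = _nifti_header("clgflow3d volume")
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine=np.diag([vol.spacing] * 3 + [1.0]), header=hdr)
    img.header.set_zooms((vol.spacing,) * 3)
    nib.save(img, str(path))


def write_field(motion: MotionField, path) -> None:
    """Write a displacement field as 4D NIfTI, last axis ordered (u, v, w).

    Values are voxel-unit displacements (stated in the header description).
    """
    arr = motion.as_array().astype(np.float32)
    hdr = _nifti_header("clgflow3d displacement (u,v,w) voxel units")
    img = nib.Nifti1Image(arr, affine=np.eye(4), header=hdr)
    nib.save(img, str(Path(path)))


def read_field(path) -> MotionField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected 4D field with last axis 3, got shape {arr.shape}")
    arr = np.asarray(arr, dtype=np.float64)
    return MotionField(arr[..., 0], arr[..., 1], arr[..., 2])
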