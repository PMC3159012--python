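"""Trilinear sampling and backward warping.

The linearized brightness-constancy constraint only holds for sub-voxel
motion, so the estimator is wrapped in a refinement loop: estimate an
increment, warp the moving frame by the accumulated field, re-estimate.
Warping is backward (pull): each output voxel samples the moving image at
its own position plus the local displacement, so every output voxel is
defined.  Coordinates falling outside the grid are clamped to the boundary
before interpolation, which avoids injecting artificial dark borders into
the temporal derivative of later passes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volumes_io import MotionField, VolumeImage

__all__ = ["trilinear_sample", "warp_volume", "accumulate_field"]


def trilinear_sample(vol: VolumeImage, x, y, z):
    """Trilinear interpolation of the volume at fractional voxel coordinates.

    Accepts scalars or congruent arrays of coordinates; out-of-range
    coordinates are clamped to [0, N-1] per axis.  Returns a scalar for
    scalar input.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("coordinates must be finite")
    nx, ny, nz = vol.dims
    coords = np.stack(
        [
            np.clip(x, 0.0, nx - 1.0),
            np.clip(y, 0.0, ny - 1.0),
            np.clip(z, 0.0, nz - 1.0),
        ]
    )
    out = ndimage.map_coordinates(vol.data, coords.reshape(3, -1), order=1, mode="nearest")
    out = out.reshape(x.shape)
    return float(out) if out.ndim == 0 else out


def warp_volume(moving: VolumeImage, field: MotionField) -> VolumeImage:
    """Backward-warp: output(x,y,z) = moving(x + u, y + v, z + w), clamped."""
    if moving.dims != field.dims:
        raise ValueError(f"dims mismatch: {moving.dims} vs {field.dims}")
    nx, ny, nz = moving.dims
    gx, gy, gz = np.meshgrid(
        np.arange(nx, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nz, dtype=np.float64),
        indexing="ij",
    )
    data = trilinear_sample(moving, gx + field.u, gy + field.v, gz + field.w)
    return VolumeImage(data, spacing=moving.spacing)


def accumulate_field(total: MotionField, increment: MotionField) -> MotionField:
    """Componentwise addition of an increment on the fixed grid.

    Each refinement pass re-warps the ORIGINAL moving frame by the running
    total, so additive accumulation avoids compounding interpolation error.
    """
    if total.dims != increment.dims:
        raise ValueError(f"dims mismatch: {total.dims} vs {increment.dims}")
    return MotionField(total.u + increment.u, total.v + increment.v, total.w + increment.w)
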