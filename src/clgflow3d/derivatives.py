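"""Spatiotemporal derivatives and the per-voxel structure-tensor products.

The brightness-constancy constraint ``Ix*u + Iy*v + Iz*w + It = 0`` is built
from forward-difference spatial derivatives of the *fixed* frame and the
frame difference as temporal derivative.  Derivative values are per voxel
step (the grid spacing h enters later, in the solver).  The outer products of
the 4-gradient populate the nine used entries of the symmetric 4x4 structure
tensor; the (4,4) entry (It^2) never enters the flow equations and is not
stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import VolumeImage

__all__ = [
    "GradientField",
    "TensorField",
    "compute_gradients",
    "compute_temporal_derivative",
    "compute_structure_tensor",
    "refresh_temporal_products",
]


@dataclass
class GradientField:
    """Per-voxel (Ix, Iy, Iz, It).

    Spatial components are forward differences, exactly zero on the last
    plane of their own axis (the stencil would look outside the domain).
    The temporal component is defined at every voxel.
    """

    ix: np.ndarray
    iy: np.ndarray
    iz: np.ndarray
    it: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.ix, self.iy, self.iz, self.it)}
        if len(shapes) != 1:
            raise ValueError("gradient components must be congruent")


_TENSOR_KEYS = ("j11", "j22", "j33", "j12", "j13", "j23", "j14", "j24", "j34")


@dataclass
class TensorField:
    """Nine unique used components of the 4x4 structure tensor J(grad4 I).

    The 3x3 spatial block [[j11,j12,j13],[j12,j22,j23],[j13,j23,j33]] is a
    rank-1 outer product per voxel before smoothing, hence positive
    semidefinite; Gaussian smoothing (a convex combination with nonnegative
    weights) preserves semidefiniteness.
    """

    j11: np.ndarray
    j22: np.ndarray
    j33: np.ndarray
    j12: np.ndarray
    j13: np.ndarray
    j23: np.ndarray
    j14: np.ndarray
    j24: np.ndarray
    j34: np.ndarray

    def components(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in _TENSOR_KEYS}

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.j11.shape

    def spatial_block(self, i: int, j: int, k: int) -> np.ndarray:
        """The 3x3 spatial sub-tensor at one voxel (diagnostic helper)."""
        return np.array(
            [
                [self.j11[i, j, k], self.j12[i, j, k], self.j13[i, j, k]],
                [self.j12[i, j, k], self.j22[i, j, k], self.j23[i, j, k]],
                [self.j13[i, j, k], self.j23[i, j, k], self.j33[i, j, k]],
            ]
        )


def _forward_diff(data: np.ndarray, axis: int) -> np.ndarray:
    out = np.zeros_like(data)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    src[axis] = slice(1, None)
    dst[axis] = slice(None, -1)
    out[tuple(dst)] = data[tuple(src)] - data[tuple(dst)]
    return out  # last plane along `axis` stays exactly zero


def compute_gradients(fixed: VolumeImage, moving: VolumeImage) -> GradientField:
    """Forward-difference spatial gradients of the fixed frame plus It.

    ``ix(x,y,z) = fixed(x+1,y,z) - fixed(x,y,z)`` for x < Nx-1, zero on the
    last x plane (analogously iy, iz); ``it = moving - fixed`` everywhere.
    """
    if fixed.dims != moving.dims:
        raise ValueError(f"dims mismatch: {fixed.dims} vs {moving.dims}")
    f = fixed.data
    return GradientField(
        ix=_forward_diff(f, 0),
        iy=_forward_diff(f, 1),
        iz=_forward_diff(f, 2),
        it=moving.data - f,
    )


def compute_temporal_derivative(fixed: VolumeImage, warped_moving: VolumeImage) -> np.ndarray:
    """Frame difference ``warped_moving - fixed``.

    Used to refresh It between outer refinement passes; the spatial
    gradients of the fixed frame are retained unchanged.
    """
    if fixed.dims != warped_moving.dims:
        raise ValueError(f"dims mismatch: {fixed.dims} vs {warped_moving.dims}")
    return warped_moving.data - fixed.data


def compute_structure_tensor(g: GradientField) -> TensorField:
    """Voxelwise outer products of the spatiotemporal gradient."""
    ix, iy, iz, it = g.ix, g.iy, g.iz, g.it
    return TensorField(
        j11=ix * ix,
        j22=iy * iy,
        j33=iz * iz,
        j12=ix * iy,
        j13=ix * iz,
        j23=iy * iz,
        j14=ix * it,
        j24=iy * it,
        j34=iz * it,
    )


def refresh_temporal_products(t: TensorField, g: GradientField, it: np.ndarray) -> TensorField:
    """New tensor with only the It-dependent channels (j14, j24, j34) rebuilt.

    The purely spatial channels are shared with ``t`` (no copy): between
    refinement passes only It changes, so only the mixed space-time products
    need recomputing and re-smoothing.
    """
    return TensorField(
        j11=t.j11,
        j22=t.j22,
        j33=t.j33,
        j12=t.j12,
        j13=t.j13,
        j23=t.j23,
        j14=g.ix * it,
        j24=g.iy * it,
        j34=g.iz * it,
    )
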