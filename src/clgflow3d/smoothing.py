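"""Separable Gaussian smoothing of structure-tensor fields.

The local-averaging step of the CLG model convolves every tensor component
with an isotropic 3D Gaussian K_rho.  Because the Gaussian factorizes, the
3D convolution is applied as three 1D passes (x, then y, then z), which is
mathematically identical to the direct triple-sum convolution with the
outer-product kernel.  Values outside the domain are treated as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .derivatives import TensorField

__all__ = ["GaussianKernel1D", "build_kernel", "convolve_separable", "smooth_tensor"]

#: guard against absurd kernel lengths from very large sigma (taps = 2K+1)
MAX_TAPS = 4097


@dataclass(frozen=True)
class GaussianKernel1D:
    """Sampled, normalized 1D Gaussian: ``taps`` of length ``2*radius + 1``."""

    taps: np.ndarray
    radius: int
    sigma: float

    def __post_init__(self) -> None:
        if len(self.taps) != 2 * self.radius + 1:
            raise ValueError("taps length must be 2*radius + 1")


def build_kernel(sigma: float, radius: int | None = None) -> GaussianKernel1D:
    """Sample a Gaussian of scale ``sigma`` and normalize to unit sum.

    ``radius=None`` picks ceil(3*sigma), large enough that the truncated
    tail is negligible without wasting work on near-zero taps.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = math.ceil(3.0 * sigma)
    radius = int(radius)
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if 2 * radius + 1 > MAX_TAPS:
        raise ValueError(f"kernel of {2 * radius + 1} taps exceeds maximum {MAX_TAPS}")
    offsets = np.arange(-radius, radius + 1, dtype=np.float64)
    taps = np.exp(-(offsets**2) / (2.0 * sigma**2))
    taps /= taps.sum()
    return GaussianKernel1D(taps=taps, radius=radius, sigma=float(sigma))


def convolve_separable(vol: np.ndarray, kernel: GaussianKernel1D) -> np.ndarray:
    """Convolve a 3D array with the separable product kernel, zero-padded.

    Equivalent to the direct sum ``sum_{i,j,k} g(i)g(j)g(k) f(x-i, y-j, z-k)``
    with f taken as zero outside the domain.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("expected a 3D array")
    out = vol
    for axis in range(3):
        out = ndimage.convolve1d(out, kernel.taps, axis=axis, mode="constant", cval=0.0)
    return out


def smooth_tensor(t: TensorField, kernel: GaussianKernel1D) -> TensorField:
    """Apply :func:`convolve_separable` independently to all nine channels."""
    if kernel.radius == 0:
        return replace(t)
    return TensorField(**{k: convolve_separable(c, kernel) for k, c in t.components().items()})
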