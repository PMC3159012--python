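"""Estimate/warp refinement loop for frame pairs and sequences.

One refinement pass = gradients -> tensor cross-products -> Gaussian
smoothing -> Jacobi solve -> backward warp.  The spatial gradients (and the
purely spatial, smoothed tensor channels j11..j23) are computed on the fixed
frame once; each pass only refreshes the temporal derivative from the
currently warped moving frame, rebuilds and re-smooths the three mixed
space-time channels (j14, j24, j34), solves for an increment from a zero
initial guess, adds it to the running total, and re-warps the original
moving frame by that total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .derivatives import (
    TensorField,
    compute_gradients,
    compute_structure_tensor,
    compute_temporal_derivative,
    refresh_temporal_products,
)
from .smoothing import GaussianKernel1D, convolve_separable, smooth_tensor
from .solver import FlowParams, clg_energy, residual_norm, solve_flow
from .volumes_io import MotionField, VolumeImage
from .warping import accumulate_field, warp_volume

__all__ = ["EstimationResult", "estimate_motion", "track_sequence"]


@dataclass
class PassDiagnostics:
    """Per-pass record: increment size, residual and energy after the solve."""

    increment_rms: float
    residual: float
    energy: float
    sweeps: int


@dataclass
class EstimationResult:
    field: MotionField
    warped: VolumeImage
    diagnostics: list[PassDiagnostics] = field(default_factory=list)


def _rms(m: MotionField) -> float:
    return float(np.sqrt(np.mean(m.u**2 + m.v**2 + m.w**2)))


def estimate_motion(
    fixed: VolumeImage,
    moving: VolumeImage,
    p: FlowParams,
    kernel: GaussianKernel1D,
) -> EstimationResult:
    """Estimate the dense displacement from ``fixed`` to ``moving``.

    Runs ``p.outer_passes`` refinement passes, each with ``p.jacobi_iters``
    Jacobi sweeps; returns the accumulated field, the final warped moving
    frame and per-pass diagnostics.
    """
    if fixed.dims != moving.dims:
        raise ValueError(f"dims mismatch: {fixed.dims} vs {moving.dims}")
    grads = compute_gradients(fixed, moving)
    tensor0 = compute_structure_tensor(grads)
    spatial = smooth_tensor(tensor0, kernel)  # j11..j23 reused every pass

    total = MotionField.zeros(fixed.dims)
    warped = moving
    diagnostics: list[PassDiagnostics] = []
    for r in range(p.outer_passes):
        it = compute_temporal_derivative(fixed, warped)
        fresh = refresh_temporal_products(tensor0, grads, it)
        if kernel.radius > 0 and r > 0:
            jrho = TensorField(
                j11=spatial.j11,
                j22=spatial.j22,
                j33=spatial.j33,
                j12=spatial.j12,
                j13=spatial.j13,
                j23=spatial.j23,
                j14=convolve_separable(fresh.j14, kernel),
                j24=convolve_separable(fresh.j24, kernel),
                j34=convolve_separable(fresh.j34, kernel),
            )
        elif kernel.radius > 0:
            jrho = spatial  # pass 0: temporal channels already smoothed above
        else:
            jrho = fresh
        log: list[float] = []
        increment = solve_flow(jrho, p, residual_log=log)
        total = accumulate_field(total, increment)
        warped = warp_volume(moving, total)
        diagnostics.append(
            PassDiagnostics(
                increment_rms=_rms(increment),
                residual=residual_norm(increment, jrho, p),
                energy=clg_energy(increment, jrho, p),
                sweeps=len(log),
            )
        )
    return EstimationResult(field=total, warped=warped, diagnostics=diagnostics)


def track_sequence(
    frames: list[VolumeImage],
    p: FlowParams,
    kernel: GaussianKernel1D,
    reference: str = "consecutive",
) -> list[EstimationResult]:
    """Motion across a sequence.

    ``reference="consecutive"`` estimates frame t -> t+1 for each adjacent
    pair; ``reference="first"`` estimates frame 0 -> t for every t >= 1.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    dims = frames[0].dims
    for f in frames[1:]:
        if f.dims != dims:
            raise ValueError("all frames must share dims")
    if reference == "consecutive":
        pairs = [(frames[t], frames[t + 1]) for t in range(len(frames) - 1)]
    elif reference == "first":
        pairs = [(frames[0], frames[t]) for t in range(1, len(frames))]
    else:
        raise ValueError("reference must be 'consecutive' or 'first'")
    return [estimate_motion(fx, mv, p, kernel) for fx, mv in pairs]
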