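"""Jacobi solution of the CLG Euler-Lagrange system.

Minimizing the CLG energy

    E(u,v,w) = integral( w^T J_rho w  +  alpha * |grad w|^2 )

with w = [u, v, w, 1] yields, per motion component, a coupled elliptic
system; discretized on the voxel grid with the 6-neighbourhood Laplacian it
becomes, at voxel i,

    (|N| + (h^2/alpha) J11) u_i  =  sum_{j in N(i)} u_j
                                    - (h^2/alpha) (J12 v_i + J13 w_i + J14),

and symmetric analogues for v and w.  The diagonal dominates (|N| >= 3,
J11 >= 0 after smoothing), so the Jacobi iteration — every unknown updated
simultaneously from the previous iterate — converges; unlike Gauss-Seidel /
SOR the update order is irrelevant, which is what makes the scheme trivially
parallel.

An optional squared-divergence penalty beta * (div w)^2 biases the solution
toward locally volume-preserving motion (cardiac muscle is nearly
incompressible).  Its Euler-Lagrange contribution adds beta/alpha times the
gradient of the divergence to each component equation; the pure second
derivative along the component's own axis is folded into the diagonal and
neighbour sum, while the cross derivatives are evaluated from the previous
iterate.

Sign convention: the discrete operator of record (``neg_laplacian``) is
(|N| f_i - sum of neighbours) / h^2, i.e. the NEGATIVE of the analytic
Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .derivatives import TensorField
from .volumes_io import MotionField

__all__ = [
    "FlowParams",
    "neg_laplacian",
    "neighbor_count",
    "jacobi_sweep",
    "jacobi_sweep_incompressible",
    "solve_flow",
    "residual_norm",
    "clg_energy",
    "divergence",
]


@dataclass
class FlowParams:
    """Parameters of the variational solve.

    alpha
        Regularization weight; larger values give smoother fields.  Scales
        with the square of the intensity range (it balances against the
        structure-tensor entries, which are squared gradients).
    beta
        Divergence-penalty weight; 0 disables the incompressibility term.
    h
        Isotropic grid spacing.
    jacobi_iters
        Fixed number of Jacobi sweeps per solve.
    outer_passes
        Number R of estimate/warp refinement passes (used by the pipeline).
    tol
        Optional relative-residual early-stop threshold, checked every 10
        sweeps; 0 (default) runs the fixed iteration count.
    border
        "count": border voxels use only their in-domain neighbours, divisor
        |N| in {3,4,5,6}.  "zeropad": out-of-domain neighbours read as zero
        with divisor 6 everywhere.
    """

    alpha: float = 2000.0
    beta: float = 0.0
    h: float = 1.0
    jacobi_iters: int = 200
    outer_passes: int = 3
    tol: float = 0.0
    border: str = "count"

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if not self.h > 0:
            raise ValueError("h must be positive")
        if self.jacobi_iters < 1 or self.outer_passes < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.border not in ("count", "zeropad"):
            raise ValueError("border must be 'count' or 'zeropad'")


def _shift(f: np.ndarray, axis: int, step: int) -> np.ndarray:
    """f shifted by `step` voxels along `axis`, zero outside the domain."""
    out = np.zeros_like(f)
    src = [slice(None)] * f.ndim
    dst = [slice(None)] * f.ndim
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    else:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    out[tuple(dst)] = f[tuple(src)]
    return out


def _neighbor_sum(f: np.ndarray) -> np.ndarray:
    """Sum of the 6-neighbourhood values, in-domain only."""
    out = np.zeros_like(f)
    for axis in range(3):
        out += _shift(f, axis, 1) + _shift(f, axis, -1)
    return out


def neighbor_count(dims: tuple[int, int, int]) -> np.ndarray:
    """|N|: in-domain 6-neighbour count (6 interior, 5 face, 4 edge, 3 corner)."""
    n = np.full(dims, 6.0)
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = 0
        sl_hi[axis] = dims[axis] - 1
        n[tuple(sl_lo)] -= 1.0
        n[tuple(sl_hi)] -= 1.0
    return n


def neg_laplacian(f: np.ndarray, h: float) -> np.ndarray:
    """(|N| f_i - sum_{j in N(i)} f_j) / h^2 — the sign-flipped Laplacian.

    Zero on constant and linear fields in the interior; on f = x^2 an
    interior voxel evaluates to -2 (the analytic Laplacian is +2).
    """
    return (neighbor_count(f.shape) * f - _neighbor_sum(f)) / (h * h)


def _axis_neighbor_count(dims: tuple[int, int, int], axis: int) -> np.ndarray:
    n = np.full(dims, 2.0)
    sl = [slice(None)] * 3
    sl[axis] = 0
    n[tuple(sl)] = 1.0
    sl[axis] = dims[axis] - 1
    n[tuple(sl)] = 1.0
    return n


def _cross_second(f: np.ndarray, ax1: int, ax2: int) -> np.ndarray:
    """h^2 * d2f/(dax1 dax2) by central differences, zero outside the domain."""
    pp = _shift(_shift(f, ax1, 1), ax2, 1)
    pm = _shift(_shift(f, ax1, 1), ax2, -1)
    mp = _shift(_shift(f, ax1, -1), ax2, 1)
    mm = _shift(_shift(f, ax1, -1), ax2, -1)
    return (pp - pm - mp + mm) / 4.0


def jacobi_sweep(motion: MotionField, jrho: TensorField, p: FlowParams) -> MotionField:
    """One true-Jacobi update of all three components from iterate k only."""
    if p.beta != 0:
        raise ValueError("jacobi_sweep handles beta == 0 only; use jacobi_sweep_incompressible")
    u, v, w = motion.u, motion.v, motion.w
    kappa = (p.h * p.h) / p.alpha
    if p.border == "count":
        nn = neighbor_count(u.shape)
    else:
        nn = 6.0
    u_new = (_neighbor_sum(u) - kappa * (jrho.j12 * v + jrho.j13 * w + jrho.j14)) / (
        nn + kappa * jrho.j11
    )
    v_new = (_neighbor_sum(v) - kappa * (jrho.j12 * u + jrho.j23 * w + jrho.j24)) / (
        nn + kappa * jrho.j22
    )
    w_new = (_neighbor_sum(w) - kappa * (jrho.j13 * u + jrho.j23 * v + jrho.j34)) / (
        nn + kappa * jrho.j33
    )
    return MotionField(u_new, v_new, w_new)


def jacobi_sweep_incompressible(
    motion: MotionField, jrho: TensorField, p: FlowParams
) -> MotionField:
    """Jacobi update for the divergence-penalized system.

    Per component (shown for u; axis 0 is its own axis):

        num = sum_{j in N} u_j
              + (beta/alpha) * (u shifted +/-1 along x)
              + (beta/alpha) * (h^2 d2v/dxdy + h^2 d2w/dxdz)   [iterate k]
              - (h^2/alpha) * (J12 v + J13 w + J14)
        den = |N| + (h^2/alpha) J11 + (beta/alpha) * n_x

    where n_x counts the in-domain x-neighbours.  With beta == 0 this is
    bit-identical to :func:`jacobi_sweep` (it delegates).
    """
    if p.beta == 0:
        return jacobi_sweep(motion, jrho, p)
    u, v, w = motion.u, motion.v, motion.w
    kappa = (p.h * p.h) / p.alpha
    ba = p.beta / p.alpha
    dims = u.shape
    if p.border == "count":
        nn = neighbor_count(dims)
    else:
        nn = np.full(dims, 6.0)

    comps = (u, v, w)
    diags = (jrho.j11, jrho.j22, jrho.j33)
    # off-diagonal tensor couplings and rhs per component
    off = (
        jrho.j12 * v + jrho.j13 * w + jrho.j14,
        jrho.j12 * u + jrho.j23 * w + jrho.j24,
        jrho.j13 * u + jrho.j23 * v + jrho.j34,
    )
    others = ((1, v), (2, w)), ((0, u), (2, w)), ((0, u), (1, v))
    out = []
    for axis in range(3):
        f = comps[axis]
        axis_sum = _shift(f, axis, 1) + _shift(f, axis, -1)
        cross = np.zeros_like(f)
        for other_axis, g in others[axis]:
            cross += _cross_second(g, axis, other_axis)
        num = _neighbor_sum(f) + ba * (axis_sum + cross) - kappa * off[axis]
        den = nn + kappa * diags[axis] + ba * _axis_neighbor_count(dims, axis)
        out.append(num / den)
    return MotionField(*out)


def _sweep(motion: MotionField, jrho: TensorField, p: FlowParams) -> MotionField:
    if p.beta > 0:
        return jacobi_sweep_incompressible(motion, jrho, p)
    return jacobi_sweep(motion, jrho, p)


def solve_flow(
    jrho: TensorField,
    p: FlowParams,
    init: MotionField | None = None,
    residual_log: list[float] | None = None,
) -> MotionField:
    """Run ``p.jacobi_iters`` sweeps from ``init`` (default all-zero).

    If ``p.tol > 0``, stops early once residual_norm / initial residual
    drops below tol (checked every 10 sweeps).  Appends the per-sweep
    residual to ``residual_log`` when a list is supplied.
    """
    motion = init.copy() if init is not None else MotionField.zeros(jrho.dims)
    r0 = residual_norm(motion, jrho, p) if p.tol > 0 else None
    for k in range(p.jacobi_iters):
        motion = _sweep(motion, jrho, p)
        if residual_log is not None:
            residual_log.append(residual_norm(motion, jrho, p))
        if p.tol > 0 and (k + 1) % 10 == 0:
            r = residual_norm(motion, jrho, p)
            if r0 == 0 or r <= p.tol * r0:
                break
    return motion


def _residual_components(
    motion: MotionField, jrho: TensorField, p: FlowParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u, v, w = motion.u, motion.v, motion.w
    inv_a = 1.0 / p.alpha
    ru = neg_laplacian(u, p.h) + inv_a * (jrho.j11 * u + jrho.j12 * v + jrho.j13 * w + jrho.j14)
    rv = neg_laplacian(v, p.h) + inv_a * (jrho.j12 * u + jrho.j22 * v + jrho.j23 * w + jrho.j24)
    rw = neg_laplacian(w, p.h) + inv_a * (jrho.j13 * u + jrho.j23 * v + jrho.j34 + jrho.j33 * w)
    if p.beta > 0:
        ba = p.beta / p.alpha
        h2 = p.h * p.h
        comps = (u, v, w)
        res = [ru, rv, rw]
        others = ((1, v), (2, w)), ((0, u), (2, w)), ((0, u), (1, v))
        for axis in range(3):
            f = comps[axis]
            own = (
                _shift(f, axis, 1)
                + _shift(f, axis, -1)
                - _axis_neighbor_count(f.shape, axis) * f
            )
            cross = np.zeros_like(f)
            for other_axis, g in others[axis]:
                cross += _cross_second(g, axis, other_axis)
            res[axis] = res[axis] - ba * (own + cross) / h2
        ru, rv, rw = res
    return ru, rv, rw


def residual_norm(motion: MotionField, jrho: TensorField, p: FlowParams) -> float:
    """RMS residual of the discrete Euler-Lagrange system; 0 iff solved exactly."""
    ru, rv, rw = _residual_components(motion, jrho, p)
    return float(np.sqrt((np.mean(ru**2) + np.mean(rv**2) + np.mean(rw**2)) / 3.0))


def _forward_grad_sq(f: np.ndarray, h: float) -> np.ndarray:
    total = np.zeros_like(f)
    for axis in range(3):
        d = _shift(f, axis, 1) - f
        # zero the last plane (no forward neighbour)
        sl = [slice(None)] * 3
        sl[axis] = f.shape[axis] - 1
        d[tuple(sl)] = 0.0
        total += (d / h) ** 2
    return total


def divergence(motion: MotionField, h: float = 1.0) -> np.ndarray:
    """du/dx + dv/dy + dw/dz, central differences (one-sided at borders)."""
    return (
        np.gradient(motion.u, h, axis=0)
        + np.gradient(motion.v, h, axis=1)
        + np.gradient(motion.w, h, axis=2)
    )


def clg_energy(motion: MotionField, jrho: TensorField, p: FlowParams) -> float:
    """Discrete CLG energy (diagnostic).

    Sum over voxels of the data term w^T J w (dropping the constant J44
    contribution, which the stored tensor omits), plus alpha times the
    squared forward-difference gradients of the motion components, plus
    beta times the squared divergence when beta > 0.
    """
    u, v, w = motion.u, motion.v, motion.w
    data = (
        jrho.j11 * u**2
        + jrho.j22 * v**2
        + jrho.j33 * w**2
        + 2.0 * (jrho.j12 * u * v + jrho.j13 * u * w + jrho.j23 * v * w)
        + 2.0 * (jrho.j14 * u + jrho.j24 * v + jrho.j34 * w)
    )
    reg = _forward_grad_sq(u, p.h) + _forward_grad_sq(v, p.h) + _forward_grad_sq(w, p.h)
    total = data + p.alpha * reg
    if p.beta > 0:
        total = total + p.beta * divergence(motion, p.h) ** 2
    return float(np.sum(total))
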