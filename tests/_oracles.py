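"""Independent brute-force oracles used only by the test suite.

Everything here is a direct scalar-loop or dense-linear-algebra
transcription of the governing equations, deliberately sharing no code
with the package implementation.
"""

from __future__ import annotations

import numpy as np

NEIGHBOR_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def direct_convolve_3d(vol: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Direct triple-sum convolution with the separable product kernel.

    f_out(x,y,z) = sum_{i,j,k} g(i) g(j) g(k) f(x-i, y-j, z-k),
    f taken as zero outside the domain.
    """
    radius = (len(taps) - 1) // 2
    nx, ny, nz = vol.shape
    out = np.zeros_like(vol, dtype=np.float64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                acc = 0.0
                for i in range(-radius, radius + 1):
                    xi = x - i
                    if not (0 <= xi < nx):
                        continue
                    for j in range(-radius, radius + 1):
                        yj = y - j
                        if not (0 <= yj < ny):
                            continue
                        for k in range(-radius, radius + 1):
                            zk = z - k
                            if not (0 <= zk < nz):
                                continue
                            acc += (
                                taps[i + radius]
                                * taps[j + radius]
                                * taps[k + radius]
                                * vol[xi, yj, zk]
                            )
                out[x, y, z] = acc
    return out


def scalar_jacobi_sweep(u, v, w, J, alpha, h):
    """Voxel-by-voxel transcription of the Jacobi update (beta = 0).

    J is a dict of 3D arrays with keys j11..j34.
    """
    nx, ny, nz = u.shape
    kappa = h * h / alpha
    un, vn, wn = np.empty_like(u), np.empty_like(v), np.empty_like(w)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                su = sv = sw = 0.0
                nnb = 0
                for dx, dy, dz in NEIGHBOR_OFFSETS:
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        nnb += 1
                        su += u[xx, yy, zz]
                        sv += v[xx, yy, zz]
                        sw += w[xx, yy, zz]
                un[x, y, z] = (
                    su
                    - kappa
                    * (
                        J["j12"][x, y, z] * v[x, y, z]
                        + J["j13"][x, y, z] * w[x, y, z]
                        + J["j14"][x, y, z]
                    )
                ) / (nnb + kappa * J["j11"][x, y, z])
                vn[x, y, z] = (
                    sv
                    - kappa
                    * (
                        J["j12"][x, y, z] * u[x, y, z]
                        + J["j23"][x, y, z] * w[x, y, z]
                        + J["j24"][x, y, z]
                    )
                ) / (nnb + kappa * J["j22"][x, y, z])
                wn[x, y, z] = (
                    sw
                    - kappa
                    * (
                        J["j13"][x, y, z] * u[x, y, z]
                        + J["j23"][x, y, z] * v[x, y, z]
                        + J["j34"][x, y, z]
                    )
                ) / (nnb + kappa * J["j33"][x, y, z])
    return un, vn, wn


def assemble_dense_system(J, alpha, beta, h, dims):
    """Dense 3N x 3N assembly of the discrete Euler-Lagrange system.

    Unknown ordering: component-major, then x-major voxel index.  Each row
    encodes (multiplied through by h^2):

        (|N| + kappa*Jcc + ba*n_ax) f_i - sum_N f_j - ba*(f along own axis)
        + kappa*(cross-tensor couplings) - ba*(cross second derivatives)
        = -kappa * Jc4

    with kappa = h^2/alpha, ba = beta/alpha, cross derivatives by central
    differences with zero outside the domain.
    """
    nx, ny, nz = dims
    n = nx * ny * nz
    kappa = h * h / alpha
    ba = beta / alpha

    def vid(x, y, z):
        return (x * ny + y) * nz + z

    diag_keys = ("j11", "j22", "j33")
    rhs_keys = ("j14", "j24", "j34")
    # coupling[c][other] = tensor key linking component c to component `other`
    coupling = {
        0: {1: "j12", 2: "j13"},
        1: {0: "j12", 2: "j23"},
        2: {0: "j13", 1: "j23"},
    }
    A = np.zeros((3 * n, 3 * n))
    b = np.zeros(3 * n)
    for c in range(3):
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    row = c * n + vid(x, y, z)
                    nnb = 0
                    for dx, dy, dz in NEIGHBOR_OFFSETS:
                        xx, yy, zz = x + dx, y + dy, z + dz
                        if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                            nnb += 1
                            A[row, c * n + vid(xx, yy, zz)] -= 1.0
                    A[row, row] += nnb + kappa * J[diag_keys[c]][x, y, z]
                    for other, key in coupling[c].items():
                        A[row, other * n + vid(x, y, z)] += kappa * J[key][x, y, z]
                    b[row] = -kappa * J[rhs_keys[c]][x, y, z]
                    if ba > 0:
                        # own-axis second derivative: -ba * (f_+1 - n_ax f + f_-1)
                        n_ax = 0
                        for step in (-1, 1):
                            pos = [x, y, z]
                            pos[c] += step
                            if 0 <= pos[c] < dims[c]:
                                n_ax += 1
                                A[row, c * n + vid(*pos)] -= ba
                        A[row, row] += ba * n_ax
                        # cross derivatives d2(other)/(d axis_c d axis_other)
                        for other in range(3):
                            if other == c:
                                continue
                            for s1 in (-1, 1):
                                for s2 in (-1, 1):
                                    pos = [x, y, z]
                                    pos[c] += s1
                                    pos[other] += s2
                                    if 0 <= pos[c] < dims[c] and 0 <= pos[other] < dims[other]:
                                        A[row, other * n + vid(*pos)] -= ba * s1 * s2 / 4.0
    return A, b


def dense_solve_motion(J, alpha, beta, h, dims):
    """Direct solve of the assembled system; returns (u, v, w) arrays."""
    A, b = assemble_dense_system(J, alpha, beta, h, dims)
    sol = np.linalg.solve(A, b)
    n = int(np.prod(dims))
    return tuple(sol[c * n : (c + 1) * n].reshape(dims) for c in range(3))


def random_tensor_field(rng, dims, grad_scale=1.0, smooth_sigma=1.0, n_products=8):
    """A realistic random structure tensor: a sum of ``n_products`` rank-1
    outer products of smooth random 4-gradients, Gaussian-smoothed
    channelwise.  The averaging mimics what heavy tensor smoothing does to
    real data and keeps the spatial block PSD and well conditioned (the
    voxelwise Jacobi coupling stays a contraction)."""
    from scipy import ndimage

    keys = ("j11", "j22", "j33", "j12", "j13", "j23", "j14", "j24", "j34")
    J = {k: np.zeros(dims) for k in keys}
    for _ in range(n_products):
        ix, iy, iz, it = (
            ndimage.gaussian_filter(rng.normal(scale=grad_scale, size=dims), smooth_sigma)
            for _ in range(4)
        )
        for key, val in (
            ("j11", ix * ix), ("j22", iy * iy), ("j33", iz * iz),
            ("j12", ix * iy), ("j13", ix * iz), ("j23", iy * iz),
            ("j14", ix * it), ("j24", iy * it), ("j34", iz * it),
        ):
            J[key] += val
    return {k: ndimage.gaussian_filter(v, smooth_sigma) for k, v in J.items()}
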