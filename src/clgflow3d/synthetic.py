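"""Analytic scenes and motion fields with exact ground truth.

Scenes are continuous intensity functions (sums of Gaussian blobs plus an
optional band-limited speckle texture) evaluated at lattice points, so a
moving frame can be produced by evaluating the *same* function at the
pre-image of each voxel under an analytic motion — no grid interpolation
ever touches the reference data, and the frame pair satisfies brightness
constancy exactly (up to the fixed-point inversion tolerance).

Conventions: a field spec defines the forward displacement d(p); the moving
frame satisfies I2(p + d(p)) = I1(p), matching the backward-warp convention
of :func:`clgflow3d.warping.warp_volume`, so the ground-truth field is d
sampled at the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .solver import divergence
from .volumes_io import MotionField, VolumeImage

__all__ = [
    "FieldSpec",
    "SceneSpec",
    "benchmark_scene",
    "render_scene",
    "advect_scene",
    "ground_truth_field",
    "gradient_mask",
    "score_field",
]

_KINDS = ("translation", "rigid_rotation", "swirl_divfree", "radial_expansion")


@dataclass(frozen=True)
class FieldSpec:
    """Analytic motion field.

    kind/params:
      - ``translation``: ``shift`` (3-vector, voxels).  Divergence 0.
      - ``rigid_rotation``: ``axis``, ``angle`` (radians), ``center``.
        Displacement divergence is 2*(cos(angle) - 1), i.e. O(angle^2) —
        volume-preserving as a map, divergence-free only to leading order.
      - ``swirl_divfree``: ``axis``, ``center``, ``strength`` (peak voxel
        displacement), ``radius`` (Gaussian envelope scale, voxels).
        Rotational displacement with a radius-only profile: exactly
        divergence-free.
      - ``radial_expansion``: ``center``, ``rate``.  Divergence 3*rate.
    """

    kind: str
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}; one of {_KINDS}")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Forward displacement d at points of shape (..., 3)."""
        p = np.asarray(points, dtype=np.float64)
        if self.kind == "translation":
            shift = np.asarray(self.params["shift"], dtype=np.float64)
            return np.broadcast_to(shift, p.shape).copy()
        if self.kind == "rigid_rotation":
            axis = np.asarray(self.params["axis"], dtype=np.float64)
            axis = axis / np.linalg.norm(axis)
            angle = float(self.params["angle"])
            center = np.asarray(self.params["center"], dtype=np.float64)
            q = p - center
            # Rodrigues rotation of q about axis
            cos_t, sin_t = np.cos(angle), np.sin(angle)
            cross = np.cross(np.broadcast_to(axis, q.shape), q)
            dot = q @ axis
            rotated = q * cos_t + cross * sin_t + dot[..., None] * axis * (1 - cos_t)
            return rotated - q
        if self.kind == "swirl_divfree":
            axis = np.asarray(self.params["axis"], dtype=np.float64)
            axis = axis / np.linalg.norm(axis)
            center = np.asarray(self.params["center"], dtype=np.float64)
            strength = float(self.params["strength"])
            radius = float(self.params["radius"])
            q = p - center
            q_par = (q @ axis)[..., None] * axis
            q_perp = q - q_par
            r = np.linalg.norm(q_perp, axis=-1)
            profile = strength * np.exp(-(r**2) / (2.0 * radius**2))
            return profile[..., None] * np.cross(np.broadcast_to(axis, q.shape), q)
        # radial_expansion
        center = np.asarray(self.params["center"], dtype=np.float64)
        rate = float(self.params["rate"])
        return rate * (p - center)


@dataclass(frozen=True)
class SceneSpec:
    """Analytic scene: Gaussian blobs + optional band-limited speckle.

    ``blobs`` is a list of ``(center, sigma, amplitude)``; ``speckle`` (if
    given) is a dict with ``cutoff`` (max spatial frequency, cycles/voxel),
    ``amplitude``, ``seed`` and optional ``n_modes`` (default 64) — a random
    sum of cosine modes, hence evaluable at arbitrary points and strictly
    band-limited.
    """

    dims: tuple[int, int, int]
    blobs: tuple = ()
    background: float = 0.0
    speckle: dict | None = None

    def __post_init__(self) -> None:
        if not self.blobs and (self.speckle is None or self.speckle.get("amplitude", 0) == 0):
            raise ValueError("scene needs at least one nonzero structure")

    def _speckle_modes(self):
        sp = self.speckle
        rng = np.random.default_rng(int(sp["seed"]))
        n = int(sp.get("n_modes", 64))
        cutoff = float(sp["cutoff"])
        # wavevectors uniform in the ball of radius 2*pi*cutoff
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        freqs = cutoff * rng.uniform(size=n) ** (1.0 / 3.0)
        k = 2.0 * np.pi * freqs[:, None] * directions
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
        amps = float(sp["amplitude"]) * rng.normal(size=n) / np.sqrt(n)
        return k, phases, amps

    def intensity(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the analytic scene at points of shape (..., 3)."""
        p = np.asarray(points, dtype=np.float64)
        out = np.full(p.shape[:-1], float(self.background))
        for center, sigma, amplitude in self.blobs:
            center = np.asarray(center, dtype=np.float64)
            d2 = np.sum((p - center) ** 2, axis=-1)
            out += amplitude * np.exp(-d2 / (2.0 * float(sigma) ** 2))
        if self.speckle is not None and self.speckle.get("amplitude", 0) != 0:
            k, phases, amps = self._speckle_modes()
            flat = p.reshape(-1, 3)
            vals = (amps * np.cos(flat @ k.T + phases)).sum(axis=1)
            out += vals.reshape(p.shape[:-1])
        return out


def benchmark_scene(speckle_seed: int = 7, dims: tuple[int, int, int] = (32, 32, 32)) -> SceneSpec:
    """The standard validation scene: three blobs over echo-like speckle.

    Emulates the salient features of a 3D ultrasound frame — bright
    structures (blob amplitudes 150-200 over background 60, i.e. roughly an
    8-bit intensity range) embedded in band-limited speckle texture strong
    enough that image gradients constrain the flow almost everywhere.
    Blob centers and radii scale with ``dims``.
    """
    nx, ny, nz = dims
    s = min(dims) / 32.0
    blobs = (
        ((0.5 * nx, 0.5 * ny, 0.5 * nz), 5.0 * s, 200.0),
        ((0.28 * nx, 0.62 * ny, 0.38 * nz), 4.0 * s, 150.0),
        ((0.69 * nx, 0.31 * ny, 0.69 * nz), 4.0 * s, 180.0),
    )
    return SceneSpec(
        dims=dims,
        blobs=blobs,
        background=60.0,
        speckle={"cutoff": 0.15, "amplitude": 60.0, "seed": int(speckle_seed), "n_modes": 96},
    )


def _lattice(dims: tuple[int, int, int]) -> np.ndarray:
    axes = [np.arange(n, dtype=np.float64) for n in dims]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def render_scene(s: SceneSpec) -> VolumeImage:
    """Evaluate the scene at lattice points."""
    return VolumeImage(s.intensity(_lattice(s.dims)))


def advect_scene(
    s: SceneSpec, f: FieldSpec, max_iter: int = 60, tol: float = 1e-12
) -> VolumeImage:
    """Moving frame: the scene seen after the motion, evaluated analytically.

    For each lattice point p, solves q + d(q) = p by fixed-point iteration
    (contractive for |grad d| < 1, true of all sensible specs here) and
    evaluates the scene intensity at q.
    """
    p = _lattice(s.dims)
    q = p.copy()
    for _ in range(max_iter):
        q_next = p - f.displacement(q)
        step = np.max(np.abs(q_next - q))
        q = q_next
        if step < tol:
            break
    return VolumeImage(s.intensity(q))


def ground_truth_field(f: FieldSpec, dims: tuple[int, int, int]) -> MotionField:
    """The forward displacement sampled at lattice points."""
    d = f.displacement(_lattice(dims))
    return MotionField(d[..., 0], d[..., 1], d[..., 2])


def gradient_mask(vol: VolumeImage, frac: float = 0.1) -> np.ndarray:
    """Voxels where |grad I| exceeds ``frac`` of its maximum.

    Outside this mask the aperture problem leaves the true motion locally
    unconstrained, so recovery there is down to the regularizer alone and
    is not scored.
    """
    gx, gy, gz = np.gradient(vol.data)
    mag = np.sqrt(gx**2 + gy**2 + gz**2)
    return mag > frac * mag.max()


def score_field(
    estimated: MotionField, truth: MotionField, mask: np.ndarray | None = None
) -> dict:
    """Endpoint-error statistics and mean |divergence| inside the mask."""
    if estimated.dims != truth.dims:
        raise ValueError("dims mismatch")
    if mask is None:
        mask = np.ones(estimated.dims, dtype=bool)
    epe = np.sqrt(
        (estimated.u - truth.u) ** 2
        + (estimated.v - truth.v) ** 2
        + (estimated.w - truth.w) ** 2
    )[mask]
    absdiv = np.abs(divergence(estimated))[mask]
    return {
        "mean_epe": float(np.mean(epe)),
        "median_epe": float(np.median(epe)),
        "p95_epe": float(np.percentile(epe, 95)),
        "mean_abs_div": float(np.mean(absdiv)),
        "n_scored": int(mask.sum()),
    }
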