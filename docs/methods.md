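# Methods

This note records the mathematical conventions, numerical choices and known
limitations of the implementation, at the level of detail a user would need
to judge whether results transfer to their data.

## Model and discretization

The estimator minimizes the combined local–global (CLG) energy

    E(u,v,w) = ∫ ( wᵀ J_ρ(∇₄I) w + α |∇w|² + β (div w)² ) dΩ,

where `w = (u,v,w,1)ᵀ`, `∇₄I` is the spatiotemporal intensity gradient and
`J_ρ = K_ρ ∗ (∇₄I ∇₄Iᵀ)` is the Gaussian-averaged structure tensor. The
local averaging (Lucas–Kanade side) makes the data term robust to noise;
the `α|∇w|²` term (Horn–Schunck side) fills in motion where the data term
is rank-deficient. With β = 0 this is the classic CLG model; β > 0 adds a
squared-divergence penalty favouring locally volume-preserving fields.

**Derivatives.** Spatial derivatives are forward differences of the fixed
frame, `Ix(x,y,z) = I₁(x+1,y,z) − I₁(x,y,z)`, set exactly to zero on the
last plane of their own axis (the stencil would leave the domain). The
temporal derivative is the plain frame difference `I₂ − I₁` and is defined
at every voxel, including spatial borders: it never looks outside the
domain, so the border-zero rule does not apply to it. Derivative values
are per voxel step; the physical spacing h enters only through the solver's
h²/α ratio. Of the symmetric 4×4 tensor only nine entries are stored; the
(4,4) entry (It²) never appears in the flow equations, and dropping it
makes the energy reported by `clg_energy` exactly zero for zero motion (the
constant offset is irrelevant to minimization).

**Smoothing.** K_ρ is a sampled, unit-normalized Gaussian applied as three
1D passes (x, y, z), mathematically identical to the direct 3D convolution
with the separable product kernel. Outside the domain the signal is taken
as zero, consistent with the solver's zero-padding option; near borders
this attenuates tensor magnitudes rather than inventing data. The kernel
parameter is exposed as a standard deviation `sigma` (some formulations
call the same parameter a "variance"; the sampled kernel here is
parametrized by its standard deviation, the common convention in the
optical-flow literature). Auto radius is ceil(3σ) — large enough that the
truncated tail is negligible — with a configurable hard cap (4097 taps) to
catch runaway parameters. Whether to renormalize the sampled kernel is a
genuine choice; normalization was chosen so that smoothing preserves
constant fields in the interior.

**Solver.** The Euler–Lagrange system is discretized with the
6-neighbourhood Laplacian. The operator of record, `neg_laplacian`, is
`(|N|·f_i − Σ_{j∈N(i)} f_j)/h²` with `|N|` the in-domain neighbour count
(6 interior, 5 face, 4 edge, 3 corner) — note this is the *negative* of
the analytic Laplacian; the Jacobi update and residual definitions are
consistent with this sign. Two border conventions exist in practice and
both are exposed via `FlowParams.border`: `"count"` (default; divisor |N|,
no ghost values — the semantics used throughout the tests) and `"zeropad"`
(divisor 6 with zero ghost values, the convention GPU implementations tend
to use because it avoids divergent branches). The residual diagnostic is
defined for the `"count"` convention.

The iteration is true Jacobi (double-buffered): all three components at
all voxels update from iterate k only. This is the order-independent,
trivially parallel choice; Gauss–Seidel/SOR converge faster sequentially
but are order-dependent. The iteration count is fixed (`jacobi_iters`,
default 200) rather than adaptive; an optional relative-residual early
stop (`tol`, checked every 10 sweeps) is off by default. Convergence note:
the voxelwise 3×3 coupling (J12, J13, J23) is not guaranteed to be
diagonally dominated for arbitrarily small α — for gradient magnitude g,
α below roughly h²·g² can make the Jacobi iteration diverge. The default
α = 2000 for intensities in a [0,255]-like range keeps the iteration a
contraction with a wide margin.

**Divergence penalty.** The β-term contributes −(β/α)·∂(div w)/∂(own axis)
to each component's equation. Discretization: the pure second derivative
along the component's own axis uses the standard 3-point stencil and is
folded into the update's neighbour sum and denominator (restricted to
in-domain neighbours); the mixed derivatives (e.g. ∂²v/∂x∂y in the
u-equation) use 4-point central differences with zero outside the domain
and are evaluated from iterate k — the pure-Jacobi choice; evaluating them
at k+1 would give a Gauss–Seidel-flavoured scheme whose result differs only
transiently, not at the fixed point. With β = 0 the incompressible sweep
delegates to the plain sweep, so the two are bit-identical by construction.
The penalty is implemented as the *squared* divergence β(div w)²: a linear
div(w) term is a null Lagrangian (its Euler–Lagrange contribution vanishes
in the interior) and cannot favour divergence-free fields; the quadratic
form is the standard incompressible-flow formulation this package follows.

**Warping.** Backward (pull) warping: output(x) = moving(x + w(x)),
sampled trilinearly, so every output voxel is defined. Out-of-range
coordinates are clamped to the boundary; returning zero instead would
inject artificial dark borders that corrupt the temporal derivative of
subsequent passes. Positive u means the structure at x in the fixed frame
appears at x + u in the moving frame. Across outer passes the increments
are accumulated *additively* on the fixed grid and each pass re-warps the
original moving frame by the accumulated total — compositional
warp-of-warp would compound interpolation error. Warm-starting the solver
from the previous increment is available (`init`) but each pass solves
from zero by default.

**Outer loop.** R passes (default 3) of: refresh It from the currently
warped moving frame; rebuild and re-smooth only the three It-dependent
tensor channels (j14, j24, j34 — the purely spatial channels depend only
on the fixed frame and are computed and smoothed once); solve; accumulate;
re-warp. Multiresolution embedding is deliberately out of scope.

## Parameters

| parameter | default | meaning |
|---|---|---|
| alpha | 2000 | smoothness weight; scales with (intensity range)², balance point of h²·J/α against |N| |
| beta | 0 | divergence penalty; 0.5·alpha is a reasonable strength for near-incompressible motion |
| sigma (ρ) | 2.33 | structure-tensor Gaussian scale; auto radius ceil(3σ) = 7, i.e. a 15-tap kernel |
| h | 1 | isotropic voxel spacing (only h²/α matters) |
| jacobi_iters | 200 | fixed sweeps per pass |
| outer_passes (R) | 3 | refinement passes; increments shrink geometrically on benchmark data |

Defaults assume intensities of order [0,255]; for unit-range data scale
alpha (and beta) by the squared intensity range.

## Synthetic validation data

`benchmark_scene` builds the standard 32³ validation volume: three
Gaussian blobs (amplitudes 150–200, σ 4–5 voxels, background 60) over
band-limited speckle (a seeded sum of 96 random cosine modes with spatial
frequency ≤ 0.15 cycles/voxel, amplitude 60). The speckle plays the role
of echo texture: it gives the data term support almost everywhere, which
is both realistic for ultrasound-like data and necessary for the
fixed-iteration-budget solver to propagate motion information across the
volume. Scenes are continuous analytic functions; the moving frame is
produced by evaluating the same function at the pre-image of each voxel
under the specified motion (fixed-point inversion of the forward
displacement map, contractive for displacement-gradient magnitude < 1), so
frame pairs satisfy brightness constancy exactly and ground truth carries
no interpolation error.

Field kinds: uniform translation; rigid rotation (note: the finite-angle
rotation *displacement* has divergence 2(cosθ−1) = O(θ²), even though the
map is volume-preserving); swirl — a rotational displacement with a
radius-only Gaussian profile, exactly divergence-free, used for the
incompressibility validation; radial expansion (constant divergence
3·rate).

What this generator does **not** emulate: multiplicative/Rayleigh speckle
statistics, attenuation and shadowing, anisotropic point-spread functions,
out-of-plane decorrelation, or intensity non-constancy between frames.
Passing the synthetic benchmarks demonstrates the estimator's correctness
under its own model assumptions, not clinical accuracy.

Scoring is restricted to a gradient mask (default: voxels whose intensity
gradient magnitude exceeds 10% of the maximum). Outside the mask the
aperture problem leaves the motion unconstrained by data, so error there
measures the regularizer's extrapolation, not the method.

## Validation problem sizes

Oracle comparisons run on 6³–8³ grids, where the assembled 3N×3N system is
solved directly and 2000 Jacobi sweeps reach machine precision; recovery
benchmarks use the 32³ scene with the default parameters (R = 3, 200
sweeps), where sub-voxel translation is recovered to ~0.1 voxel median
endpoint error and the β = α/2 penalty reduces mean |div| by ~15% on the
divergence-free swirl. These sizes were chosen so the whole validation
suite runs in well under a minute while exercising every code path at
full fidelity.

## Known limitations

- Jacobi can diverge if α is far too small for the intensity scale (loss
  of voxelwise diagonal dominance); the solver does not detect this —
  watch the residual diagnostics.
- Fixed iteration counts mean very low-texture volumes under-converge;
  raise `jacobi_iters` or `tol`-based stopping for such data.
- No multiresolution: motions much larger than ~1 voxel per pass rely
  entirely on the warp refinement loop and may lock onto the wrong local
  minimum.
- Isotropic voxels only; anisotropic NIfTI inputs are rejected rather than
  resampled. Displacement output is in voxel units.
- Intensity constancy is assumed; gain drift between frames biases the
  estimate.
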