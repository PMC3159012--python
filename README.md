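# clgflow3d

Dense 3D motion estimation for volumetric image sequences by the combined
local–global (CLG) variational optical-flow method, with an optional
incompressibility (divergence) penalty and an iterative estimate/warp
refinement loop. The target setting is biomedical imaging — e.g. real-time
3D echocardiography, where local myocardial motion must be recovered from
consecutive intensity frames — but the method applies to any pair or
sequence of 3D scalar volumes.

## The model

Brightness constancy between two frames, linearized, gives the 3D optical
flow constraint

    Ix·u + Iy·v + Iz·w + It = 0,

which determines only the gradient-direction projection of the motion (the
aperture problem). The CLG approach regularizes it in two complementary
ways: locally, by averaging the outer product of the spatiotemporal
gradient with a Gaussian of scale ρ,

    J_ρ(∇₄I) = K_ρ ∗ (∇₄I ∇₄Iᵀ),      ∇₄I = (Ix, Iy, Iz, It)ᵀ,

and globally, by a Horn–Schunck smoothness term, minimizing

    E(u,v,w) = ∫ ( wᵀ J_ρ w + α |∇w|² + β (div w)² ) dx dy dz,

with `w = (u, v, w, 1)ᵀ` and `|∇w|² = |∇u|² + |∇v|² + |∇w|²`. The β term
(off by default) biases the field toward locally volume-preserving motion,
appropriate for near-incompressible tissue such as cardiac muscle.

The Euler–Lagrange equations form a coupled elliptic system, discretized
with the 6-neighbourhood Laplacian and solved by **Jacobi iteration** —
every unknown updated simultaneously from the previous iterate:

    u_i ← [ Σ_{j∈N(i)} u_j − (h²/α)(J12 v_i + J13 w_i + J14) ] / ( |N| + (h²/α) J11 ),

and symmetrically for v and w, where `|N|` is the number of in-domain
neighbours of voxel i. Because the linearization only holds for sub-voxel
motion, the whole estimate is wrapped in R refinement passes: solve for an
increment, add it to the running total, re-warp the original moving frame
by the total (backward warping, trilinear interpolation), refresh the
temporal derivative, repeat. Spatial gradients are computed once, on the
fixed frame.

The `synthetic` module generates fully analytic test data — blob + speckle
scenes advected by translations, rigid rotations, divergence-free swirls or
radial expansions — so every stage is verifiable against exact ground truth
without any external dataset.

## Worked example

```python
import clgflow3d as cf

scene  = cf.benchmark_scene(speckle_seed=7)                    # 32³ blobs + speckle
motion = cf.FieldSpec("translation", {"shift": (0.6, -0.4, 0.3)})

fixed  = cf.render_scene(scene)
moving = cf.advect_scene(scene, motion)
truth  = cf.ground_truth_field(motion, scene.dims)

params = cf.FlowParams(alpha=2000.0, jacobi_iters=200, outer_passes=3)
kernel = cf.build_kernel(2.33)                                 # radius 7

result = cf.estimate_motion(fixed, moving, params, kernel)
scores = cf.score_field(result.field, truth, cf.gradient_mask(fixed, 0.1))

print(f"median EPE : {scores['median_epe']:.3f} voxels")
for r, d in enumerate(result.diagnostics, 1):
    print(f"pass {r}: increment RMS {d.increment_rms:.4f}, residual {d.residual:.2e}")
```

prints

```
median EPE : 0.135 voxels
pass 1: increment RMS 0.7229, residual 8.98e-04
pass 2: increment RMS 0.0508, residual 8.87e-05
pass 3: increment RMS 0.0210, residual 3.66e-05
```

The recovered field matches the true (0.6, −0.4, 0.3)-voxel shift to about
a tenth of a voxel (median endpoint error over the voxels where the image
gradient is strong enough to constrain the flow), and the per-pass
increment RMS collapses as the refinement loop converges: pass 1 captures
the bulk of the motion, later passes correct the linearization error.

## Command line

```
clgflow3d estimate --fixed F.nii.gz --moving M.nii.gz \
    --alpha 2000 --sigma 2.33 --jacobi-iters 200 --passes 3 \
    --out-field field.nii.gz --out-warped warped.nii.gz
clgflow3d track --frames f0.nii.gz --frames f1.nii.gz --frames f2.nii.gz \
    --mode consecutive --out-prefix flow
clgflow3d synth --spec scene.yaml --field-spec field.yaml \
    --out-fixed I1.nii.gz --out-moving I2.nii.gz --out-truth gt.nii.gz
```

Volumes are 3D NIfTI (or raw float32 + JSON sidecar, x fastest);
displacement fields are 4D NIfTI with the last axis ordered (u, v, w), in
voxel units. All flags can come from a YAML/JSON `--config` file.

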