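# Methods

## Model and assumptions

The registration model is landmark LDDMM under geodesic shooting.  A
deformation `φ(·,1)` is the endpoint of a flow `dφ/dt = v(φ,t)` whose
velocity lies in the reproducing-kernel Hilbert space of a Gaussian kernel
with width `σ_K`.  For `N` landmark pairs the whole flow is determined by
the initial momenta `p₀ ∈ R^{N×d}` through the canonical Hamiltonian system

    dqᵢ/dt =  Σⱼ K(qᵢ,qⱼ) pⱼ
    dpᵢ/dt = −Σⱼ ∇_{qᵢ}K(qᵢ,qⱼ) (pᵢ·pⱼ),

with `H(q,p) = ½ Σᵢⱼ pᵢᵀK(qᵢ,qⱼ)pⱼ` conserved along trajectories.  The
fitted objective is the geodesic energy `½ p₀ᵀK(q₀)p₀` plus the
Mahalanobis matching penalty `Σₙ (yₙ−qₙ(1))ᵀΣₙ⁻¹(yₙ−qₙ(1))`; `Σₙ`
encodes how much each correspondence is trusted (soft landmarks).

Assumptions this rests on:

* landmark correspondences are correct up to noise of scale `√Σₙ` — there
  is no intensity term to recover from mismatched pairs;
* one kernel width per region describes the deformation's regularity
  (no spatially varying kernels);
* per-region deformations are individually diffeomorphic; global topology
  is *not* guaranteed after composition and is restored post hoc.

Composition uses Shepard (inverse-distance-power) weights on distances to
eroded region cores; with exponent `μ > 1` the blended field is C¹.  The
residual-compensation loop subtracts `w₁β` times the inverse-consistency
residual from each field per iteration — on constant-translation fields the
error contracts by exactly `|1 − 2βw₁|` per step — while Gaussian-smoothed
demons terms penalize drift of the cortex mask (`w₂`) and of sub-cortical
structures (`w₃`).  As printed in the update equation, the residual term is
not smoothed; only the demons velocities are (an optional whole-update
smoothing flag exists, default off).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `kernel_width` (σ_K) | 5 px (2D pipeline) / 0.25-covariance generic API uses caller's value | mm or px | velocity-field regularity; ≈ the fold scale to be matched.  For the 4-px ribbon, 8 px proved too stiff across the ribbon and 4 px too local (checked on the aligned phantom); ~5 mm is a sensible 3D starting point |
| `covariance` (Σₙ) | 1e-4 px² (pipeline) / 0.25 mm² (`optimize_momentum` default) | mm² | landmark trust. The phantom's correspondences are exact by construction, so the pipeline uses a tight value; real mesh-derived landmarks carry ~0.5 mm matching noise, hence the soft generic default |
| `shooting_steps` | 20 | — | RK4 steps; H-drift is O(steps⁻⁴), < 1 % at 20 |
| `optimizer` | `lbfgs` (pipeline), `gd` (generic default) | — | L-BFGS with the same adjoint gradient is used by the pipeline because the tight covariance makes plain descent ill-conditioned |
| `landmark_cap` | 2000 | — | uniform thinning bound; kernel sums are dense O(N²) |
| `se_radius` | 2 voxels | — | structuring-element radius for region cores |
| `mu` | 4 | — | Shepard exponent (µ > 1 for C¹) |
| `w1, w2, w3` | 0.5, 0.3, 0.2 | — | residual / cortex-demons / sub-structure-demons weights, normalized to sum 1 |
| `beta` | 0.5 | — | residual step scale |
| `alpha` | 1.0 | — | demons denominator stabilizer |
| `sigma_cc`, `sigma_sub` | 2 mm | mm | smoothing of the demons terms |
| `mask_presmooth` | 1 voxel | voxels | Gaussian applied to binary masks so their gradients are meaningful |
| `max_iter` (enforcement) | 200 | — | iteration budget; stop at `target_nonpositive` (0 for the phantom; for 3D brains a tolerated count of ~1300 voxels trades regularity against ~86 % cortical Dice) |

## The phantom generator

`make_gyrus_phantom` emulates a single cortical gyrus in 2D cross-section:
a U-shaped ribbon of width 4 px (≈ the cortical ribbon at 1 mm T1
resolution) on a 128×128 grid, split into three sub-regions of arc-length
fractions (0.3, 0.4, 0.3).  The moving and fixed variants differ in arch
half-width (17 vs 18.5 px), fold depth (51 vs 46 px), a third-harmonic
wiggle (3 px) and an x-skew (2 px) on the fixed centerline — a smooth,
genuinely nonlinear shape difference of up to ~8 px displacement that a
global affine cannot absorb.  The misaligned variant shifts the moving
ribbon 12 px along x, so the folds have essentially no initial overlap
(Dice 0.03).

Construction: the fixed image is rasterized from its analytic centerline;
the dense correspondence between the two geometries (matched arc-length
fractions × matched normal offsets) is extended to the plane by Gaussian
kernel ridge regression (σ = 6 px, ridge 1e-2), checked fold-free, and the
moving image is the fixed image resampled through that map (plus the exact
integer shift).  Landmarks are sampled every ~2 px along both offset
(±1.5 px) boundary curves of each region on the fixed geometry and carried
to the moving side as preimages under the generator map, so the published
pairs are exactly the correspondence realized in the images.  Because the
moving image is a resampled copy, nearest-neighbour label warping under an
accurate estimated field "snaps back" onto the fixed rasterization; with
two independent rasterizations the sub-pixel quantization of the 1-px grid
alone would bound the achievable whole-mask Dice near 95 % no matter how
accurate the warp.

What passing the phantom shows: sub-0.1-px recovery of a smooth nonlinear
warp from exact, dense, two-sided boundary landmarks, robustness of the
region-based pipeline to gross initial misalignment, and topology
preservation of the composed field.  What it does not show: performance
under landmark mismatch or parcellation error, 3D folding geometry,
multi-region interaction beyond three adjacent labels, or any
intensity-driven behaviour — real-brain accuracy claims need real MRI and
a surface pipeline.

`make_known_deformation` provides an independent ground-truth family for
recovery tests: Gaussian-filtered white noise scaled to a set amplitude and
rejected unless the Jacobian perturbation stays below 1 (fold-free by
construction).

## Numerical choices

* Coordinates are voxel-centered, 0-based; physical = origin + index ×
  spacing; displacements are stored in mm so fields transfer across
  resolutions.  To resample a moving image on a fixed grid the supplied
  field must map fixed → moving coordinates.
* Field composition samples with multilinear interpolation and
  boundary-clamps out-of-grid positions (keeps residuals finite); image
  warping fills out-of-grid samples with background.
* Jacobians use spacing-aware central differences (one-sided on faces).
* The momentum gradient is the adjoint of the *discrete* RK4 integrator
  (exact to machine precision against finite differences), not the
  continuous adjoint.
* The reverse dense field advects template-grid points along the
  time-reversed, sign-flipped velocity rather than inverting the forward
  field numerically; inverse-consistency is measured (99 % of grid points
  round-trip within 0.1 px on two-landmark fits), not assumed.
* Rasterization interpolates the stored landmark trajectory linearly in
  time at RK4 stage points.
* Ties in nearest-vertex matching break to the lowest vertex id; Shepard
  weights floor distances at 1e-9 to avoid 0⁰ next to cores; a region whose
  core erodes to nothing falls back to its undilated mask with a warning.
* The degenerate inputs — empty masks, absent labels, singular affines,
  non-finite fields mid-iteration — raise with the stage and region named.

## Design decisions that were genuinely open

* The velocity-space operator is realized as a Gaussian kernel, making σ_K
  the single regularity knob.
* The global affine is estimated from the matched landmarks themselves
  (least squares) rather than by intensity registration — the pipeline has
  exact correspondences available; an externally computed affine can be
  supplied through the file interfaces instead.
* Per-region translations come from region-mask centroids.
* Background voxels participate in the IDW blend through the same
  "otherwise" formula as transition areas, so the global field covers the
  whole grid.
* Whether fold counts are restricted to a brain mask is left to the caller
  (optional mask argument); the phantom numbers count the whole grid.
* On this phantom the IDW-composed fields are already fold-free before
  enforcement (the affine absorbs the misalignment and adjacent regional
  fields agree in the transition bands), so the loop's fold-removal is
  exercised on a deliberately folded two-region fixture in the tests; the
  phantom runs verify the already-bijective fixed point and the final
  zero counts.

## Known limitations

* Dense O(N²) kernel sums cap practical landmark counts at a few thousand
  per region (hence the thinning cap).
* Gradient-descent mode converges slowly under very tight covariances; use
  the L-BFGS mode.
* No resampling between grids of different spacing; inputs must be
  pre-resampled.
* The demons terms assume reasonably overlapping masks after composition;
  they are local and cannot recover gross mismatches.
* 2D and 3D are supported by the field machinery, but the shipped phantom
  and its calibration are 2D.
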