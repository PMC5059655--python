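# Methods

This note documents the models, numerical choices and limitations behind
`dtreg`, in the order the pipeline runs them.

## Signal model and tensor estimation

Diffusion is modeled per voxel as a single Gaussian profile: the
displacement density over time `t` is
`G(x; D, t) = (4πt)^(-3/2) det(D)^(-1/2) exp(-xᵀD⁻¹x / 4t)` with `D` the
3×3 symmetric positive-definite diffusion tensor (mm²/s).  The measured
signal for gradient `g` at b-value `b` is `S = S0 exp(-b gᵀDg)`; the
diffusion time is absorbed into `b` and never enters the fit.

Estimation is ordinary least squares on log-signals with the 7-column
design (six tensor terms, log-S0 intercept).  OLS rather than weighted
least squares is deliberate: the wild bootstrap's hat-matrix/leverage
algebra is exact for OLS, and the bootstrap is the point of the pipeline.
Voxels with any non-positive signal are excluded from the fit and
flagged.  Negative eigenvalues arising under noise are clamped to zero
and flagged, keeping FA and OVL well defined.  Eigenvector signs are
never relied upon anywhere: every consumer is antipodally symmetric.

A single-shell acquisition with one b=0 has a structural quirk worth
knowing: the b=0 row's indicator lies in the design column space, so its
leverage is exactly 1 and its residual identically 0.  The bootstrap
treats such saturated rows as carrying no resampling information (factor
0); the standalone rescaling operation raises instead, since a caller
asking to rescale a saturated row usually has a design problem.

## Corrected wild bootstrap

Residuals `r_i` are rescaled by `(1-h_i)^(-1/2)` so each has the variance
of a true error, then corrected with a score function ψ:
`r̃*_i = r̃_i + γ⁻¹ h_i ψ(r̃_i)`, `γ = ∫ψ(x)f(x)dx` with `f` the residual
density.  Choices made here:

* **Random multipliers.** The corrected-residual construction is named a
  wild bootstrap, whose standard form randomizes residual signs; we adopt
  independent Rademacher ±1 multipliers per observation as the default.
  `multiplier="none"` gives the literal deterministic addition for
  comparison.  With ψ≡0 the scheme reduces bitwise to the classical
  leverage-rescaled wild bootstrap; additionally zeroing `h` gives the
  plain residual bootstrap.
* **Score function.** ψ is configurable among `zero`, `identity`,
  `square`; `identity` is the default.
* **γ estimation.** Plug-in: the sample mean of `ψ(r̃_i)` evaluates the
  integral under the empirical density.  The estimate falls back to
  `γ = 1` whenever `|γ̂| < max(1e-12, 0.05·mean|ψ(r̃)|)`.  The relative
  guard matters: an odd ψ on a *finite* near-symmetric sample gives a
  tiny but nonzero mean, and dividing by it amplifies the correction by
  orders of magnitude — in testing this randomized replicate principal
  directions at every noise level.  A fixed absolute threshold cannot
  catch this because the failure scale depends on the residuals' units.
* **Residual space.** Corrections act on log-signal residuals, the space
  of the linear fit.  Replicates are exponentiated back to signal space.
* **Spatial coupling.** Replicates are drawn independently across voxels.

Convergence contract (tested): the replicate ensemble's mean log-signal
approaches the fitted log-signal as the replicate count grows (Rademacher
multipliers have mean zero), and the angular dispersion of replicate
principal directions grows monotonically with injected noise.

## Probabilistic tractography

Step directions are sampled from the posterior
`p(v̂_i | v̂_{i-1}, D) ∝ p(D | v̂_i, θ) p(v̂_i | v̂_{i-1})` over a
subdivided-icosahedron sphere (642 vertices by default; at least 100
required).  The likelihood is interpreted as an axially symmetric
("constrained") Gaussian profile: a tensor whose principal axis is fixed
at the candidate direction, with axial diffusivity λ₁, radial
diffusivity (λ₂+λ₃)/2, baseline S0 and residual variance all plugged in
as point estimates from the local fit — the Dirac treatment of the
nuisance parameters θ.  The prior is proportional to cos θ on the
forward hemisphere and zero behind, which also enforces the 90° turning
limit; it is uniform for the first step.

Each step first interpolates the raw DWI trilinearly at the current
point, refits the tensor there, draws a corrected wild-bootstrap
replicate of the local signals, and evaluates the posterior on the
replicate — so the sampled direction reflects measurement uncertainty
resampled from the data.  Tensor quantities are always recomputed from
interpolated signals, never interpolated directly.

Defaults: step 0.5× the smallest voxel dimension; termination on
FA < 0.15, sharp turn (empty posterior support), leaving the mask, or
2000 steps; bidirectional seeding (two half-streamlines along ±first
direction, concatenated).  All tracking is batched: active streamlines
advance in lock-step with the posterior evaluated as three matrix
products against precomputed sphere-gradient couplings, which is what
makes 10³–10⁴-streamline runs take seconds in pure numpy.

Connectivity between regions A and B is the fraction of `n` streamlines
seeded uniformly in A that enter B — rejection sampling over path space;
its standard error empirically scales as `1/√n` (tested at
n ∈ {100, 400, 1600}).  Visitation maps count distinct streamlines per
voxel (each streamline increments a voxel at most once).

## Symmetric diffeomorphic registration

The transform between visitation-density images I (moving) and J (fixed)
is decomposed into two half-paths φ₁, φ₂ meeting at the temporal
midpoint.  Optimization is greedy and symmetric: per iteration both
images are warped to the midpoint, the windowed normalized
cross-correlation (radius 2) and its analytic gradient give ascent
forces for both halves, forces are fluid-smoothed (σ = 3 voxels),
composed into the half fields, and the total fields elastically smoothed
(σ = 1 voxel).  Three resolution levels (×4/×2/×1) run 100/70/40
iterations; each update step is capped at 0.25 voxel.  A `metric="ssd"`
switch replaces the similarity with the (negative) squared difference.
If similarity worsens for 10 consecutive finest-level iterations the
best-so-far fields are returned with a divergence flag.

Window statistics use the effective (truncated) window size near the
image boundary; without that correction the constant-padding bias makes
even `b = 2a + 5` score below 1.

Inverses come from fixed-point iteration (`inv(x) = -d(x + inv(x))`, 20
iterations, 0.01-voxel tolerance); the full forward map is φ₁∘φ₂⁻¹.
Tested contracts: self-registration < 0.05 voxel mean displacement;
inverse-consistency residual < 0.1 voxel mean / 0.25 voxel at the 95th
percentile; recovery of known ≤ 4-voxel synthetic warps to < 1 voxel
mean endpoint error; swapping inputs yields mutual inverses within 0.2
voxel.  A separate scaling-and-squaring integrator exposes stationary
velocity-field flows (zero velocity → identity; ±v flows compose to
identity within 0.05 voxel).

**What is registered.** Whole-volume visitation-count maps, transformed
`log(1+count)` and Gaussian-smoothed (σ = 1 voxel).  Tracking counts are
Poisson-like; the log transform compresses the dynamic range so the
similarity is not dominated by high-count cores.  An affine initializer
(phase-correlation translation seed, then staged Powell refinement of a
12-parameter model on global NCC; rigid before scale/shear, because a
joint search lets shear absorb rotation) is available for inputs that
are not yet roughly aligned; the synthetic pipeline skips it since its
subject/template pairs share a grid by construction.

**Tensor reorientation.** Warping a tensor volume resamples the six
components by pull-back, then conjugates each tensor by the rotation
part (orthogonal polar factor, via SVD) of the local forward Jacobian —
finite-strain reorientation.  Eigenvalues are exactly preserved;
voxels with singular local Jacobians are flagged and left unrotated.
Preservation-of-principal-direction is intentionally not implemented.

## Evaluation metrics

* **Dyadic coherence.** Per voxel, the mean over subjects of `e₁e₁ᵀ` has
  eigenvalues β₁ ≥ β₂ ≥ β₃ and `κ = 1 - sqrt((β₂+β₃)/(2β₁))` ∈ [0, 1]
  (1 = identical, → 0 random).  Sub-epsilon β₂+β₃ mass (relative to β₁)
  is snapped to zero before the square root, which otherwise amplifies
  eigensolver rounding of rank-1 dyadics to ~1e-9.
* **OVL.** Per voxel `Σⱼ λⱼλ'ⱼ(eⱼ·e'ⱼ)² / Σⱼ λⱼλ'ⱼ`, averaged over the
  mask; voxels where both tensors are null are excluded from the average.
  The index-paired form is kept exactly as defined (the swapped-e₁/e₂
  hand value 1/6 pins it down); note it is basis-dependent for
  *degenerate* spectra, where the eigenbasis itself is arbitrary.
* **CC.** Non-centered cosine form `ΣX₁X₂/√(ΣX₁²ΣX₂²)` over white-matter
  voxels (template FA > 0.2), computed for FA and trace maps; a
  `centered=True` option gives the Pearson form but is not the default.
* **Empirical CDFs** of per-voxel κ and OVL values accompany the scalars.

In the end-to-end pipeline, metrics are evaluated over the intersection
of the template's WM mask with the subject's valid-data mask: a warped
subject can pull out-of-field (null) voxels into the template's WM, and
a zero-trace voxel inside the mask corrupts the non-centered CC with
spurious zeros that say nothing about alignment.

## Synthetic phantom

The generator emulates a small DTI acquisition: 40×40×20 voxels at 2 mm,
15 gradient directions (Fibonacci hemisphere) at b = 1000 s/mm² plus one
b = 0, S0 = 1000.  Two tubular bundles — one straight (radius 4 voxels,
eigenvalues (1.7, 0.3, 0.3)×10⁻³ mm²/s) and one arc (radius 3,
(2.0, 0.4, 0.4)×10⁻³) — sit in an isotropic 0.7×10⁻³ background; inside
a tube the principal axis is the local centerline tangent.  The two
tracts carry *different* diffusivities on purpose: with a single
eigenvalue set, the trace map is one constant across white matter and
the trace cross-correlation saturates near 1 with no sensitivity to
alignment, making it useless as an evaluation criterion.  Distinct
axial/radial diffusivities across tracts are also the physiologically
realistic case.  Noise is Rician — `sqrt((S+n₁)² + n₂²)` with n₁, n₂
zero-mean Gaussians of std σ — matching magnitude MRI; σ ∈ {0, 20, 50}
are the levels used in tests (SNR ∞, 50, 20 at b=0).

Ground-truth warps are sums of Gaussian bumps (per-component random
amplitudes), tapered to exactly zero displacement at the grid boundary,
scaled to a requested maximum (default bump width 4× the maximum
displacement, which keeps the Jacobian safely positive; positivity is
verified by a finite-difference scan and violation raises).  Bump
centers are restricted to the central half of the grid — the boundary
taper cancels edge bumps, and warps that never touch the bundles make
the registration comparison vacuous.  The inverse field is computed by
fixed-point iteration and verified to compose to identity within 0.05
voxel.

**Subject construction in the pipeline.** The synthetic "subject" is an
independent acquisition of warped anatomy: the template's tensor field
is warped with finite-strain reorientation and the subject's DWI is then
simulated from it with fresh noise.  Warping the template's DWI
channel-wise instead would leave the diffusion orientations unrotated
relative to the deformed anatomy — measurably worse than doing nothing:
undoing such a warp with the exact inverse *increased* orientation error
in testing.  The channel-wise operation remains available
(`warp_phantom`) for scalar-level round-trip checks.

**What the phantom does not capture.** Realistic brain geometry, partial
volume beyond tube-edge interpolation, crossing-fiber voxels inside a
single tensor (the model is single-tensor by design), eddy currents,
motion, susceptibility distortion, and multi-shell acquisitions.
Passing tests on the phantom therefore validate the algorithms and their
contracts, not clinical-grade performance on real data.

## Problem sizes and determinism

Desk-scale sizes are used throughout: the 40×40×20 grid (versus
128×128×64 for a real acquisition), 1000–1600 streamlines per
connectivity estimate, 1500 streamlines per visitation map,
100/70/40 registration iterations.  The end-to-end run takes ~30 s on
one CPU.  Every stochastic component takes an explicit seed; the
pipeline derives per-stage seeds from one global seed by stage-name
hashing (CRC32, reduced mod 2³¹), so full runs — and independent reruns
of any single stage — are bit-identical.  Streamlines are stored as TRK
(float32 world mm, hence the 1e-4 mm round-trip tolerance) with a
plain-text fallback.

## Known limitations

* The constrained-likelihood interpretation (axially symmetric tensor,
  plug-in nuisances) is one reading of a Bayesian direction posterior;
  fuller treatments would marginalize over θ.
* Sphere discretization quantizes directions to ~4° at 642 vertices;
  noise-free tracking inherits a ≲2° systematic from vertex snapping.
* The greedy half-field scheme optimizes a stationary field per half
  rather than the full time-varying velocity formulation.
* γ's plug-in estimator is pooled (or per-point in tracking) and noisy
  at 16 observations; the relative fallback guard trades a small bias
  for stability.
* OVL on degenerate spectra depends on the eigensolver's basis choice
  (see above); identical inputs are handled exactly.
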