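# Methods

## Local model

The voxel-wise forward model treats the diffusion-attenuated signal as a
partial-volume mixture of one isotropic compartment and up to N (default 3)
fibre compartments.  The isotropic "ball" carries a Gamma distribution of
diffusivities with mean `d_m` and standard deviation `d_std` (both mm²/s);
its attenuation is the Laplace transform `(β/(β+b))^α` with `β = d_m/d_std²`,
`α = d_m·β`.  This adds a single parameter over a mono-exponential ball yet
captures non-mono-exponential decay across shells, which is what makes
multi-b-value data representable.  For `d_std < 1e-7 mm²/s` the code
switches to the analytic limit `exp(-b·d_m)`: at that scale the two agree
to machine precision while `α, β` would overflow.

Each fibre compartment is the impulse response of an axially symmetric
tensor reparameterised by the mean eigenvalue `λ_m` and the radial/axial
ratio `λ_R = λ₂/λ₁ ∈ (0,1)`.  The fODF is a sum of spherical delta
functions, so the spherical convolution collapses to the kernel evaluated
at each fibre orientation; the quadrature oracle in the test suite checks
this closed form against dense numerical integration of the convolution to
better than 1e-3 relative.  The model ties `λ_m = d_m` so the two
compartment families share a mean diffusivity and stay identifiable; large
genuine differences in isotropic diffusivity are absorbed by `d_std`.  A
single average kernel anisotropy is fitted across all b-shells — in reality
the ideal kernel varies with b, and a shell-dependent kernel is a known,
deliberate omission.

Signals (not attenuations) are the unit of prediction throughout, since
`S0` is itself a sampled parameter.  `b = 0` points are ordinary
measurements with attenuation 1.  Orientations are stored as unit vectors;
spherical angles appear only in reporting.

## Spatial model and neighborhoods

An LR voxel intersecting P HR voxels with fractions `a_p` is predicted by
the signal-weighted ratio `S_l^LR/S0^LR = Σ a_p S_{l,p}^HR / Σ a_p S0_p^HR`,
evaluated at the LR gradient table.  The ratio form (rather than a weighted
sum of attenuations) is less sensitive to mixing signal from tissues with
different baselines, which matters at tissue boundaries.  The
implementation requires an integer per-axis LR/HR voxel ratio, so `a_p =
1/P` and the HR grid partitions into disjoint neighborhoods — the unit of
joint inference, processed independently (and therefore parallelisable and
order-independent).  Data not meeting the integer-ratio constraint are
block-mean downsampled (magnitude signals, not log-signals, matching the
physics of a coarser acquisition) — in the intended 3T/7T use case, the LR
data are downsampled to twice the HR voxel size.  HR voxels outside the
brain mask still participate in their neighborhood when at least one
sibling is in-mask; they receive fitted parameters but are flagged, which
preserves `Σ a_p = 1` without re-weighting ambiguity.

## Likelihood

Magnitude MRI with SENSE1-style reconstruction carries Rician noise, so
each measurement contributes `log τ + log Y − τ(Y²+S²)/2 + log I₀(τ·Y·S)`.
The Bessel term uses the exponentially scaled `i0e`, keeping the
log-likelihood finite at arbitrarily high SNR.  Each HR voxel has its own
precision `τ_p`, and the LR voxel its own `τ^LR`; the datasets are
conditionally independent given the parameters, so the joint is a sum.
`Y ≤ 0` entries are treated as missing data (excluded from the likelihood):
a proper Rician density is supported on Y > 0, and this also makes
all-zero (background) voxels well-defined inside fused neighborhoods.

## Priors

* `S0`, `τ` — flat on (0, ∞).
* `f₁` — uniform on [0, 1]; `f_n, n ≥ 2` — ARD `p ∝ 1/f^w` with the default
  severity `w = 1` and the relaxed alternative `w = 0.8`, which detects
  more crossings at some cost in precision.  An evaluation floor of 1e-8 on
  the fraction keeps the improper density finite in proposals.
* `d_m` — Gamma(shape 3, scale 0.25e-3 mm²/s), peaking at 0.5e-3 and with
  mean 0.75e-3, covering parenchymal diffusivities.
* `d_std` — ARD `p ∝ 1/d_std`, encouraging a single diffusivity per voxel.
* `λ_R` — Gaussian `N(μ_λ, σ_λ²)` truncated to (0, 1) since it is an
  eigenvalue ratio of an anisotropic kernel.  Defaults `μ_λ = 0.13`,
  `σ_λ = 0.03`; `learn_response_prior` re-estimates them per dataset from
  the most anisotropic voxels of a coherent-WM mask: the mask is eroded
  once with a 6-connected element (erode-then-threshold order; single-voxel
  masks fall back to no erosion), the top 50% of FA values are kept and the
  mean/std of `(λ₂+λ₃)/2λ₁` returned.  The estimate is scale-invariant in
  the eigenvalues.
* Orientations — uniform on the sphere in the voxel-wise model.  In the
  fusion model each neighborhood carries an equal-weight mixture of M
  (default 3) Watson distributions shared by all its fibre orientations;
  modes and concentrations are hyper-parameters sampled with everything
  else.  Hyper-hyper-priors: uniform-on-sphere for the modes and
  log-uniform on κ ∈ [0.01, 5000] (a log-uniform cannot include 0; the
  lower edge is far below any practically identifiable concentration).
  The Watson normaliser uses the Kummer function directly for κ < 600 and
  its asymptotic expansion above, keeping log-densities finite at κ up to
  the prior ceiling.

## MCMC

One-parameter-at-a-time Metropolis.  Positive scale-like parameters (`S0`,
`d_m`, `d_std`, `τ`, `S0^LR`, `τ^LR`, Watson κ) take multiplicative
log-normal random walks with the `log x' − log x` asymmetry correction in
the acceptance ratio (equivalently: a Gaussian walk on the log with the
Jacobian accounted for); `λ_R` and the fractions take additive Gaussian
walks, rejected outside their support (including `Σf > 1`, which keeps the
simplex geometry of the prior without reparameterisation); orientations
take symmetric random rotations (angle ~ N(0, s), uniformly random axis).
Orientation proposals are a mixture kernel: 80% local rotations, 20% draws
uniform on the sphere.  The uniform component is a symmetric independence
proposal that lets a near-empty compartment (whose likelihood is flat in
its orientation) hop between well-separated fODF modes that local rotations
cannot reach; without it, chains in crossing regions occasionally collapse
all compartments onto one orientation.

Proposal scales adapt toward ~50% acceptance every 40 iterations during
burn-in only (multiplying by `exp(rate − 0.5)`, clamped to [1e-4, 3]), so
the sampling phase is strictly Markovian.  The default schedule is 5000
burn-in iterations and 1250 sampling iterations thinned by 25 — 50 retained
draws per parameter.  Chains are initialised from a log-linear DTI fit
(principal orientation, remaining compartments on the secondary/tertiary
eigenvectors — for a crossing these span the right plane — MD for `d_m`, b0
mean for `S0`, b0 scatter for `τ`).  Each voxel/neighborhood derives its
random stream from `SeedSequence((master_seed, index))`, making results
bit-reproducible and independent of processing order.  Whether the Watson
hyper-parameters should be updated jointly with or separately from the
voxel parameters is an open choice; here they are Metropolis updates
interleaved at the end of each sweep.

Posterior summaries: scalar modes come from a Gaussian-KDE over the draws;
orientation point estimates are the principal eigenvector of the mean dyad
`(1/T)Σ v vᵀ`, which respects the v ≡ −v symmetry.  The 95% cone of
uncertainty is the 95th percentile (linear interpolation) of the angles
between each draw's dyad and the mean dyad.  Fibre identity across draws
follows the sampler's compartment labels; no relabelling is applied, so
label switching inflates per-compartment cones in deep crossings — a known
caveat.  Crossing counts threshold the posterior-mean fractions at f > 5%;
ROI summaries report the fraction of voxels with ≥2 and ≥3 supported
compartments.  Cone summaries pool all supported compartments by default
(first-compartment-only is available), since it is ambiguous which
convention a given report uses.

## Synthetic phantoms

The generator emulates the two protocol families the fusion model targets:
an LR set with 3 shells (b = 1000/2000/3000 s/mm²) × 90 directions + 5 b0,
and an HR set with 2 shells (b = 1000/2000) × 65 directions + 6 b0, on
aligned grids with an integer voxel ratio (default 2 per axis).  Directions
come from electrostatic repulsion of antipodal pairs, deterministic given a
seed.  Truth fields: `single` (f = 0.7 along +x), `crossing90`/`crossing60`
(f = 0.35 + 0.35), `three_way` (f = 0.25 × 3), `boundary_csf` (a WM slab
against a fast, broadly distributed isotropic slab with f_AN = 0 — the
WM/CSF border stress case) and `fanning`.  White-matter voxels use d_m =
1.0e-3 mm²/s, d_std = 1e-4, λ_R = 0.13, S0 = 1000.

LR data are generated through the same signal-ratio spatial model used in
inference (the LR baseline is the volume-weighted HR baseline), which
separates inference correctness from model-adequacy questions; a
model-mismatch stress case is available by shifting the noise-free HR
signal field trilinearly by a sub-voxel offset before LR synthesis (the
shift is applied to the signal field rather than the parameter field, since
interpolating orientations is ill-defined).  Noise is Rician — the
magnitude of (S + ε₁, ε₂) with ε ~ N(0, σ²) and σ = S0/SNR at b = 0; the
tests verify the σ√(π/2) noise floor at S = 0, i.e. the generator and the
likelihood assume the same noise model.  Default SNRs in the fusion
experiments are 15–20 (HR) and 40 (LR), reflecting the intended asymmetry:
a noisy fine grid fused with a clean coarse one.

What the phantoms do not contain: EPI distortion, eddy currents, motion,
PSF blurring along the phase-encode direction, relaxation differences
between field strengths, or spatially varying coil sensitivity.  Passing
the recovery and fusion tests therefore demonstrates correctness of the
model and sampler under the model's own assumptions, not robustness to
real-world artefacts; misalignment is the only mismatch mode exercised.

## Problem sizes and numerical choices

The recovery and fusion experiments in the test suite and in
`scripts/acceptance.py` run at desk scale: 50 voxels for single-fibre
recovery (burn-in 500, 250 sampling iterations thinned by 5 → 50 draws),
a 6×6×6 crossing phantom (27 fused neighborhoods of P = 8; burn-in 400,
200 sampling iterations thinned by 4) for the fusion comparison and a
4×4×2 three-way phantom for the ARD contrast.  These sizes give stable
medians and ROI fractions while keeping a full run in minutes on one CPU;
the retained-draw count (50) matches the default schedule's.  Gradient
schemes keep the full protocol sizes (275 and 136 volumes) since the
likelihood cost, not the grid, is what dominates.

Tolerances: unit-vector checks at 1e-6; the Gamma-ball mono-exponential
switch at d_std = 1e-7 mm²/s; shell grouping at 100 s/mm² (b-values closer
than this share a shell); grid alignment at 1e-3 relative voxel-size
tolerance.  Degenerate inputs: neighborhoods whose weighted baseline sums
to zero raise; voxels with all-zero data are skipped (voxel-wise) or
treated as fully missing (fusion); isotropic DTI fits fall back to
arbitrary eigenvector frames, which the samplers tolerate since
orientations with f ≈ 0 carry no likelihood.

## Known limitations

Single shared kernel anisotropy across shells; no PSF or relaxation
modelling in the spatial combination; no fractional/overlapping LR-HR
geometry (integer ratio only); no compartment relabelling in posterior
summaries; CPU-only (the per-neighborhood independence makes process-level
parallelism trivial, but none is built in).  On real paired datasets the
LR constraints are expected to cost some effective resolution; that is a
property of real acquisitions and is not assertable on these phantoms.
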