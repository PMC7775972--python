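# Methods

## Signal model and units

The forward model is the standard single-compartment GRE signal: magnitude
decay M0·e^(−TE·R2\*) plus a noise floor, and linear phase evolution
φ(TE) = φ0 + 2πΔf·TE.  Fields are carried as frequency offsets Δf in Hz
throughout (ΔB_z in Tesla is Δf/(γ/2π), with γ/2π = 42.577 MHz/T);
susceptibility is carried in ppb.  At 7 T, 1 ppb of unit dipole response
corresponds to 42.577e6·7·1e−9 ≈ 0.298 Hz.  All Hz↔ppb conversions go
through `AcquisitionParams.hz_per_ppb`.

The dipole response is D(k) = 1/3 − (k·b̂)²/|k|² on the discrete FFT grid
with D(0) := 0: the spatial mean of χ is unobservable, which is also why
the final maps are referenced to a zero whole-brain mean (post-mortem
brains offer no pathology-free internal reference region).  Dipole
convolutions are periodic; the forward simulator zero-pads by a factor of
2 by default to suppress wrap-around (`pad_factor`, config-exposed).

## Synthetic phantom

The phantom emulates a whole brain immersed in a signal-free,
susceptibility-matched perfluorocarbon inside a spherical container: an
ellipsoidal brain with a white-matter core (inner ellipsoid at
`white_fraction` = 0.75 of the semi-axes), a grey-matter shell, a
cortical-ribbon cap patch within the grey shell, and optional air bubbles
(ppm-scale χ, zero signal).  Default tissue values — χ(surround/white/grey/
ribbon) = 0/−30/+20/+50 ppb, R2\* = 1/45/35/50 s⁻¹, M0 = 0/1000/800/800 —
are plausible round numbers for fixed tissue at 7 T; no literature
consensus pins them down, so every value is config-exposed rather than
hard-coded.  The default noise level used in cohort studies
(σ = 20 per complex channel, i.e. white-matter magnitude SNR 50) is a
realistic figure for long post-mortem protocols.

Simulated artefacts: per-coil smooth complex sensitivities (Gaussian
magnitude, linear phase ramp) with constant per-coil phase offsets;
per-repeat global frequency offsets (B0 drift is prescribed, not thermally
modelled); per-echo phase-encode translations applied by Fourier phase
ramp (subvoxel-capable, so the alignment stage can be tested at subvoxel
shifts); additive complex Gaussian noise, which yields Rician magnitudes
after combination.

What the phantom does **not** emulate: k-space undersampling/GRAPPA,
gradient nonlinearity, susceptibility anisotropy, microstructural
(non-linear-in-TE) phase evolution, and convoluted cortical folding.
Passing recovery tests therefore demonstrates correctness of the
processing chain, not performance on every feature of real data.

## Coil combination and alignment

First-echo phase subtraction removes any echo-time-independent phase
exactly (verified to <1e−10 rad in noiseless tests).  The complex sum over
coils is magnitude-weighted by |S_c(TE₁)| by default (`weighted=False`
gives the plain sum): the choice maximizes SNR without reintroducing
offsets; both variants satisfy the same contracts.

Translation estimation uses subpixel Fourier cross-correlation
(upsampled-DFT refinement, default resolution 1/50 voxel) of sum-of-squares
magnitudes.  Echo-to-echo alignment keeps only the phase-encode component
of the estimated shift — the drift mechanism translates along that axis
only — and resamples the *first* echo into each later echo's frame, so the
later echoes that feed all downstream stages are never interpolated.
Repeat alignment estimates one 3-vector per repeat against the second echo
of repeat 1 and applies it to all of that repeat's volumes (phase through
its complex exponential, respecting wrapping).  Rotations are out of
scope; the holder-based experimental setup constrains motion to
translations.

k-space slice truncation keeps the central ceil(n/factor) band along the
slice axis and rescales amplitudes so band-limited signals are preserved;
it reproduces the resolution-matching step (e.g. 208 slices at 0.55 mm →
104 at 1.1 mm).

## Field mapping

The per-voxel fit minimizes the complex residual over (φ0, Δf) with the
magnitude taken from the data (not fitted); it is solved by Gauss–Newton
on the 2-parameter phase model (the normal matrix is
parameter-independent, so iterations are cheap and vectorized across all
masked voxels), tolerance 1e−10 on the parameter step, max 50 iterations.
Non-convergent voxels keep their initialization and are flagged; they are
natural candidates for the φ0-based mask refinement, since φ0 doubles as a
goodness-of-fit indicator.

Initialization: the phase difference between the first two effective
echoes and the first effective echo itself are spatially unwrapped and
converted per the two-echo closed form.  Only those two images are ever
unwrapped — they carry far fewer wraps than later echoes.  Unwrapping is
quality-guided region growing (quality = negative local phase-derivative
variance), exact modulo 2π within each connected region; the global 2πk of
each region is fixed so the region's median lands in [−π, π] (a uniformly
large offset over the *entire* region remains genuinely ambiguous;
disconnected regions carry independent offsets).  An independent
cross-check against scikit-image's 3-D unwrapper is part of the test
suite.

Masking: threshold at `threshold_frac` (default 0.1) of the 99th-percentile
first-echo magnitude, largest connected component, holes filled.  The φ0
refinement threshold defaults to 1.0 rad; neither threshold has a
published reference value, so both are config parameters.  The readout
phase-gradient fit is restricted to the mask (the out-of-mask surround
carries no reliable phase) and removes each later echo's own fitted line
independently, using the integer TE′ₙ/TE′₁ ratios of the protocol (a
warning and fractional prediction handle non-multiple spacings).

Per-repeat Δf maps are averaged rather than averaging raw phase: a
per-repeat global drift offset then averages benignly instead of causing
phase cancellation, and a locally corrupted repeat influences the mean by
at most 1/n.  The per-repeat whole-mask mean Δf and its increments form
the drift diagnostic.

## Background removal and inversion

v-SHARP: spherical-mean-value kernels with radii descending from
`max_kernel_mm` (default 12 mm, the protocol value) to one voxel in
one-voxel steps; each voxel is filtered with the largest sphere fully
inside the mask; deconvolution divides by (1 − SMV) of the largest kernel
with Fourier components truncated where |1 − SMV| < `reg_param`
(default 0.02 — the published parameter's units are ambiguous, and this
package interprets it as the dimensionless truncation threshold).  The
output mask is the one-voxel erosion.

A fundamental property worth stating explicitly: SHARP-family filtering
removes *all* components of the field that are harmonic inside the mask —
including the harmonic part of the field generated by shape-scale internal
structure (a uniformly magnetized ellipsoid produces a uniform, hence
harmonic, internal field).  On phantoms whose χ structure spans the whole
mask (the white-core/grey-shell default), within-mask contrast is strongly
attenuated after background removal; compact features (ribbon patch,
bubbles, blobs) are preserved.  Real cortical structure is closer to the
compact regime, but absolute referenced χ values should still be
interpreted as relative contrast.  Recovery tests that assert
quantitative round trips therefore use either an identity (full-grid) mask
or compact sources; group-contrast tests difference the same ROI across
subjects, which cancels the common attenuation.

TKD divides by D clamped at `threshold` (default 0.2, common practice;
sign(0) := +1).  The clamp underestimates compact sources by ~20–25% at
threshold 0.2 (shrinking with the threshold); this bounded bias is
asserted, not corrected.  The streak-reduced scheme runs a
lightly-clamped first pass (threshold 0.1), flags voxels above the 99.5th
|χ| percentile *and* an absolute floor of 300 ppb (well above tissue,
well below bubbles — so with no strong sources the scheme degenerates
exactly to TKD), subtracts the strong-source forward field, and inverts
the residual at threshold 0.2.  On bubble phantoms the tissue-region RMSE
is roughly 2.5× lower than one-pass TKD; the contract is the paired
inequality, not equivalence to any particular published implementation.

## R2\* mapping

Non-negative (projected Levenberg–Marquardt, vectorized over voxels)
least squares of M0·e^(−TE·R2\*) + noise over all six echoes;
initialization noise = min(M), M0 = max(M) − noise, R2\* from a two-point
log-linear estimate on echoes 1 and 3.  Non-negativity bounds are imposed
as the physical choice.  Fitting uses repeat-averaged magnitudes (after
repeat alignment); per-repeat fits feed the T2\* drift report
(mean T2\* over voxels with R2\* > 1 s⁻¹ to avoid 1/0; no correction is
applied below a 1% change threshold).

A caveat established by simulation: with this 6-echo protocol, at
moderate decay (R2\* ≈ 40 s⁻¹) and SNR ≈ 50 the last-echo signal sits an
order of magnitude above the Rician floor, and there the floor parameter
is weakly identified and biases R2\* upward by more than the Rician floor
biases a 2-parameter fit (≈ +3 s⁻¹ vs ≈ −0.1 s⁻¹ in mean over 1000
voxels; confirmed against an independent bounded least-squares
implementation).  The floor term's clear benefit is in floor-dominated
decays — when the late echoes genuinely plateau (fast R2\* or low SNR),
the 2-parameter model is forced into a compromise slope while the floor
model recovers all three parameters; the unit tests demonstrate both
regimes.

## Statistics

Scaled-MAD outlier rejection uses 1.4826·median(|x − median|) with k = 3
and a strict inequality, so all-equal inputs lose nothing while a deviant
minority above a zero MAD is excluded (matching the common implementation
of the rule).  A warning fires if more than half an ROI is rejected.
SAF standardization is within-batch z-scoring with the sample SD
(ddof = 1; switchable).  Partial correlation is computed by OLS double
residualization, which equals the first-order closed form to 1e−12 (tested
against pingouin).  Group contrasts: Welch's t with Satterthwaite df and
Hedges's g = pooled-SD Cohen's d × (1 − 3/(4ν − 1)), ν = n_a + n_b − 2,
positive when the first group's mean is larger.  p-values are two-tailed,
α = 0.05, with no multiple-testing correction — matching the analysis
design this pipeline supports.

## Problem sizes and determinism

Recovery experiments run on 32³ grids at 2 mm (64³ at 1 mm for the
field-fit experiment) — geometry scaled so the brain-to-kernel and
source-to-voxel ratios exercise the same regimes as full-resolution data
while keeping simulations cheap; cohort studies use 9 + 3 subjects and 20
replicates.  Every stochastic step takes an explicit seed
(`numpy.random.default_rng`); pipelines re-run bit-identically for a fixed
seed, and results are independent of voxel chunking.

## Known limitations

- No GRAPPA/undersampling reconstruction: simulated data are fully
  sampled per coil.
- Translation-only registration; no rotations or nonlinear warps.
- Single-compartment phase model; microstructural frequency dispersion is
  out of scope by design.
- Whole-brain-mean referencing makes χ a relative quantity; shape-scale
  contrast is attenuated by background removal (see above).
- Histology enters as tabulated stained-area fractions; no slide-to-MRI
  spatial registration.
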