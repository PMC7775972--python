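# pmqsm — post-mortem whole-brain QSM and R2\* mapping

`pmqsm` is a processing pipeline for quantitative susceptibility mapping
(QSM) and R2\* relaxometry of whole post-mortem brains scanned with a
multi-coil, multi-echo 3D gradient-echo (GRE) sequence at 7 T.  Post-mortem
acquisitions differ from in vivo scanning in ways that break standard QSM
tooling: there is no skull and no CSF reference region, air bubbles in the
immersion liquid create strong dipole sources, and very long scan sessions
drive B0 drift (via passive-shim heating) that misaligns echoes and repeats
and biases the phase evolution.  The pipeline addresses each of these with
appropriately constrained corrections, and ships with a physics-based
synthetic phantom generator so that every stage is testable by parameter
recovery — no scanner data required.

It is aimed at researchers processing post-mortem GRE data (or building
QSM methodology) who want a transparent, fully scriptable implementation
with a simulator that exercises the same code paths.

## The model

The complex GRE signal per coil c, echo n and repeat r is

    S_c(r⃗, TEₙ) = C_c(r⃗) · M0(r⃗) · e^(−TEₙ·R2*(r⃗)) · e^(i[φ0_c(r⃗) + 2π(Δf(r⃗) + drift_r)·TEₙ])

with Δf = (γ/2π)·ΔB_z the frequency offset induced by the tissue
susceptibility distribution χ through the unit dipole response

    Δf̃(k) = f0 · D(k) · χ̃(k),    D(k) = 1/3 − (k·b̂)²/|k|²,  D(0) := 0.

Processing stages:

1. **Coil combination** — the coil-specific phase offset φ0_c is removed
   exactly by subtracting each channel's first-echo phase, giving
   offset-free phase images at effective echo times TE′ₙ = TEₙ − TE₁
   (6.6 … 33 ms for the TEs = 2, 8.6, 15.2, 21.8, 28.4, 35 ms protocol);
   channels are combined by a magnitude-weighted complex sum, magnitudes
   root-sum-of-squares.  Before subtraction the first echo is registered to
   each later echo (translation along the phase-encode axis only — the
   drift mechanism cannot shift any other axis); later echoes are never
   interpolated.
2. **Field mapping** — per voxel, (φ0, Δf) minimize
   ‖S − |S|·e^(i(φ0 + 2πΔf·TE′))‖² across the effective echoes.  The fit is
   initialized from the spatially unwrapped first effective echo and the
   unwrapped phase difference of the first two, which keeps it on the right
   branch even beyond the aliasing limit of π per echo spacing
   (π/(2π·6.6 ms) ≈ 75.76 s⁻¹).  Large residual |φ0| flags unreliable
   voxels (bubbles, vessels) which are removed from the mask; a linear
   readout-direction phase gradient (eddy currents / readout mistiming) is
   fitted and removed.  Per-repeat field maps are averaged — robust to B0
   drift, which appears as the per-repeat mean Δf in the drift diagnostic.
3. **QSM** — v-SHARP (variable spherical-mean-value kernels, 12 mm max,
   regularized deconvolution) removes harmonic background fields; dipole
   inversion by thresholded k-space division (TKD) or a two-pass
   streak-reduced scheme that separates bubble-strength sources from weak
   tissue contrast; χ (ppb) is referenced to a zero whole-brain mean.
4. **R2\*** — per voxel, non-negative least squares of
   M(TE) = M0·e^(−TE·R2\*) + noise over all six echoes of the
   repeat-averaged magnitudes, with a T2\* drift report across repeats.
5. **ROI statistics** — ROI means after scaled-MAD outlier rejection
   (1.4826·MAD, k = 3), within-batch standardization of histology
   stained-area fractions, Pearson and first-order partial correlations,
   Welch's t and Hedges's g for group contrasts.

## Worked example

Simulate a "diseased" subject (cortical ribbon patch with +30 ppb χ and
+15 s⁻¹ R2\* over grey matter) and a control, run both through the full
pipeline, and compare ribbon ROI means:

```python
from pmqsm.study import simulate_subject, ribbon_contrast_study

d = simulate_subject(1, diseased=True)
c = simulate_subject(2, diseased=False)
print(d, c)
g = ribbon_contrast_study(7)   # 9 disease vs 3 control subjects
print(g)
```

prints

```
disease subject: ribbon chi 2.6 ppb, R2* 52.5 s^-1
control subject: ribbon chi -1.5 ppb, R2* 39.0 s^-1
cohort replicate: g_chi=7.24 g_r2s=22.60
```

The ribbon χ difference between subjects (≈4 ppb here) is the recovered
group contrast: within-subject shape-scale χ structure is strongly
attenuated by background-field removal (see `docs/methods.md`), so
absolute ROI values are not comparable to the simulated tissue values, but
the between-group direction is robust — positive Hedges's g for both χ and
R2\*.  R2\* is recovered near-quantitatively (52.5 vs a simulated 50 s⁻¹).

The same pipeline is scriptable from the shell:

```
pmqsm simulate --config phantom.yaml --out sim/
pmqsm run --config phantom.yaml --in sim/ --out maps/
pmqsm roi-stats --maps maps/ --rois rois/ --histology saf.csv --out stats/
```

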