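# raddwi

Simulation and test–retest repeatability analysis of **radially sampled**
and **multi-shot EPI** diffusion-weighted MRI of the mouse abdomen.

## The problem

Quantitative diffusion-weighted imaging (DWI) of abdominal organs in
freely breathing mice is hard: respiratory motion corrupts the
diffusion-sensitized signal, and at high field the off-resonance
sensitivity of echo-planar readouts adds coherent ghosting. Two
spin-echo DWI protocols address this differently — a radially sampled
acquisition (RAD: 64 readout points × 101 views, reconstructed by
filtered back-projection at 64×64) that disperses motion errors as
diffuse streaks, and a 4-shot interleaved EPI acquisition (128×128)
that is faster and higher-SNR but shows shot-to-shot phase-error ghosts.
This package implements the full quantitative chain for both protocols
as a simulation study, so that every processing choice can be validated
against known ground truth:

1. **Digital phantom** — a 32×32 mm² abdominal section with a tumor,
   spinal muscle, a water tube and a 1-butanol tube, each with its own
   proton density, diffusivity and chemical shift (`raddwi.phantom`).
2. **Acquisition simulator** — complex k-space for both trajectories
   under a periodic respiratory-motion model with prospective gating,
   five b-values (0.64, 535, 1071, 1478, 2141 s/mm²), both
   diffusion-gradient polarities, shot-to-shot phase errors,
   off-resonance phase accrual and complex Gaussian noise
   (`raddwi.acquisition`).
3. **Reconstruction** — zero/first-order phase correction and ramp-filtered
   back-projection for radial data; interleave reassembly and inverse FFT
   for EPI; Rayleigh-corrected SNR measurement (`raddwi.recon`).
4. **ADC mapping** — geometric-mean combination of the two gradient
   polarities (cancelling background-gradient cross terms) and a
   pixel-wise three-parameter fit of

   S(b) = S₀ exp(−b·D) + A

   where D is the apparent diffusion coefficient (ADC) and A absorbs the
   Rician noise floor of magnitude images (`raddwi.adcfit`).
5. **Repeatability statistics** — within-subject SD and CV and the 95%
   repeatability coefficient of paired test–retest ADC measurements,

   SD_ws = √(Σ ΔD² / 2n), CV_ws = √(Σ (ΔD/m)² / 2n), RC = 1.96·√2·SD_ws,

   plus Bland-Altman summaries with limits at bias ± RC, kernel density
   estimates of pixel-wise tumor ADC, and cross-protocol OLS correlation
   (`raddwi.repeatability`).
6. **Experiment driver** — a virtual test–retest cohort (n subjects × 2
   sessions × protocols) with seeded biological jitter, producing the
   per-tissue repeatability table (`raddwi.experiment`).

The numbered scripts under `analysis/` run these stages as a narrative
(simulate a session, reconstruct and map it, compare gated vs non-gated
acquisition, run the full cohort); their tables land under `results/`.

## Worked example

```python
import raddwi as rd

spec  = rd.default_phantom()              # tumor, muscle, water, butanol
maps  = rd.rasterize(spec, 64)            # 0.5 mm pixels
model = rd.RespirationModel()             # 0.675 s period, gated windows
ks    = rd.simulate_radial_kspace(maps, rd.radial_params(), model, seed=1)
stack = rd.fbp_reconstruct(rd.correct_radial_stack(ks))
pmaps = rd.fit_stack(stack)
rois  = rd.roi_masks(maps, erode=2)
for tissue in ("tumor", "water", "butanol", "muscle"):
    mean, sd, n = rd.roi_stats(pmaps, rois[tissue])
    print(f"{tissue:8s} ADC = {mean*1e3:.4f} x1e-3 mm^2/s")
```

Output of this noiseless, gated run:

```
tumor    ADC = 1.3025 x1e-3 mm^2/s
water    ADC = 3.2000 x1e-3 mm^2/s
butanol  ADC = 0.4404 x1e-3 mm^2/s
muscle   ADC = 1.8005 x1e-3 mm^2/s
```

i.e. the pipeline returns each compartment's true diffusivity (tumor
1.3, water 3.20, butanol 0.44, muscle 1.8, all ×10⁻³ mm²/s) to a few
tenths of a percent; with noise at the protocols' realistic SNR the ROI
means acquire a small upward bias that the test suite characterizes.

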