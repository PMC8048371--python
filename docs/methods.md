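# Methods

This note documents the models, numerical choices and known limitations
of the `raddwi` pipeline. Everything quantitative stated here is
computed by the test suite or the analysis scripts.

## Digital phantom

The phantom is a 2-D axial section through a mouse abdomen: an
elliptical body (diffusivity 2.0×10⁻³ mm²/s), a tumor ellipse
(1.3×10⁻³), a spinal-muscle band (1.8×10⁻³), and two 5-mm reference
tubes under the animal containing water (3.20×10⁻³, the literature
value for free water at 37 °C) and 1-butanol (0.44×10⁻³). Tube inner
radius is 2.1 mm; compartment placement is a geometric convention.
Butanol's aliphatic proton resonances (3.51, 1.56, 1.25, 0.8 ppm, most
signal near 1.56 ppm) are collapsed into a single effective offset of
−3.1 ppm relative to water; one effective resonance is enough to
reproduce the EPI off-resonance corruption. T1/T2 weighting is not
modeled separately — the zero-b amplitude S₀ is a free fit parameter,
so it absorbs all relaxation weighting.

Rasterization samples compartment membership at pixel centers
(winner-takes-priority; equal-priority overlap is an error), with an
optional ×4 oversampling flag that averages parameter values over
sub-pixels. Pixel-center sampling makes disk areas converge to the
analytic value (within 3% at a 256 matrix, tested) and keeps
rasterization idempotent.

## Acquisition simulation

k-space is synthesized by **direct discrete Fourier evaluation** of the
rasterized phantom — exact, desk-scale, and the same code path serves as
the oracle for reconstruction tests. Radial views are straight lines
through k = 0 at 101 angles in equal increments over 180°; EPI is a
Cartesian raster split into 4 interleaves. The radial line evaluation
exploits the equispaced k-offsets (geometric-progression phase
accumulation) for speed; the result is identical to the naive
evaluation to ~1e-13 relative.

**Respiration** is a periodic displacement d(t): zero during the first
`quiescent_fraction` (default 0.6) of each period (default 0.675 s,
physiological 0.6–0.75 s range), and a smooth sin² bump otherwise,
directed along a unit vector (default anterior–posterior), amplitude
1 mm by default. Prospective gating schedules one view/shot per
`tr_resp_periods` periods at the middle of the quiescent window;
non-gated scans use a uniform repetition time of the same mean duration
with a seeded 1–5% incommensurability factor standing in for the free
drift between scanner clock and breathing, so events sweep all
respiratory phases.

Motion enters the signal three ways, all derived from the instantaneous
trace at the event time:

1. **Rigid in-plane translation** — a linear phase e^(−2πi k·d(t))
   across the sampled line (the only spatial effect; through-plane
   motion and elastic deformation are out of scope).
2. **Bulk diffusion-encode phase** — a single per-view/per-shot phase
   φ = s·v(t)·√(b/b_max) with v the velocity along the displacement
   direction. For EPI the constant and linear (readout-direction)
   per-shot phase errors are drawn ~N(0, φ²), which is what produces
   interleave ghosts at multiples of matrix/n_shots lines.
3. **Intravoxel phase dispersion** — an attenuation e^(−φ²/2), the
   Gaussian-phase-spread counterpart of (2). This is the component that
   survives phase correction and is responsible for the elevated
   apparent ADC of non-gated scans: with the default scale
   s = 0.5 rad/(mm/s), a noiseless non-gated radial run reads the water
   compartment ≈ 3.9–4.0×10⁻³ mm²/s against a gated 3.20 — the
   magnitude of the gated/non-gated contrast this simulator is meant to
   emulate. No quantitative motion-phase model was available to fix s
   independently; it is a documented tunable.

Off-resonance (EPI only): pixels are grouped by chemical shift; each
group's k-space lines acquire phase 2π·Δf·t_line with
Δf = shift·1e-6·(γ/2π)·B₀ and t_line the within-shot echo-train time
(echo spacing = matrix_read / bandwidth). At 4.7 T the −3.1 ppm butanol
offset is ≈ −620 Hz, which displaces/disperses the tube along the phase
encode and reproduces its corruption in EPI but not in radial images
(tested: the butanol region loses > 50% intensity while on-resonance
tissue is preserved to < 5%).

An optional background-gradient weighting `background_gradient_b`
(s/mm²) gives the two diffusion-gradient polarities effective exponents
(√b ± √b_bg)², i.e. a cross term ±2√(b·b_bg); it exists to demonstrate
that the geometric-mean combination cancels the cross term exactly
(tested analytically and through the reconstruction).

Noise is complex circular Gaussian per sample; magnitudes downstream
are therefore Rician, which is what motivates the offset A in the
signal model. Averages are independent noise realizations combined
complex-valued before reconstruction. Every stochastic element is
driven by an explicit integer seed; identical seeds give bit-identical
k-space.

The paper-level protocol constants carried as defaults: TE 30/26 ms,
Δ = 14.4 ms, δ = 9 ms, b = (0.64, 535, 1071, 1478, 2141) s/mm² (the
minimum b suppresses perfusion contributions), FOV 32 mm, radial
64×101/1 average at 50 kHz, EPI 128×128/4 shots/16 averages at 250 kHz,
B₀ = 4.7 T. The Stejskal–Tanner helper b = γ²g²δ²(Δ−δ/3) is provided
for unit bookkeeping but the simulator takes b directly.

## Reconstruction

**Radial.** Each view receives zero- and first-order phase correction.
The stack-level correction is *echo-referenced*: the echo-peak
magnitude is recentered to the middle readout index (an integer shift —
a no-op for trajectories without timing errors, since the DC sample of
a non-negative object dominates every view) and the phase at the peak
is zeroed, which removes view-to-view bulk phase errors while leaving
the object's own linear phase (its position) untouched. A per-view
variant that also estimates and removes a continuous linear-phase ramp
(lag-one autocorrelation estimator) is provided and tested as an
operation; it is deliberately *not* used in the pipeline because, on a
multi-compartment object, the per-view ramp estimate is a nonlinear
functional of the projection rather than a rigid-shift ramp, and
removing it shifts projections inconsistently (measured: it corrupts
the small off-center butanol tube's ADC by ≈ ×2.5 even without noise).

Filtered back-projection: per view, an inverse DFT gives the parallel
projection; the projection is convolved with the **analytic
band-limited ramp kernel** h(t) = ½ sinc(t) − ¼ sinc²(t/2) (the exact
inverse transform of |k| limited to ±½ cycle/sample) evaluated on an
8× oversampled, non-periodic radius grid, then back-projected with
linear interpolation and weighted π/V. Using the analytic kernel on a
wide grid rather than an FFT-domain filter avoids the N-periodic
wrap-around of DFT-filtered projections, which otherwise contaminates
corner pixels. Measured accuracy: a band-limited phantom is recovered
with 0.01% NRMSE and energy conserved to 0.01%; a sharp disk conserves
energy to ≈ 1% (the remainder is unsampled corner energy); the
interpolating implementation agrees with brute-force exact evaluation
of the same integral to well under 5% and with the classical
real-sinogram back-projector from scikit-image to a few percent.
A Hann-apodized variant of the filter is available (default off).
Output is the pixel-wise magnitude, consistent with Rician statistics.

**EPI.** Interleaves are reassembled by their trajectory row indices
and inverted with a 2-D FFT (the half-pixel offset of pixel centers is
carried as an explicit phase ramp, making the round trip exact to
machine precision). Even/odd-echo (readout-reversal) correction is
assumed ideal and not simulated; only shot-to-shot errors — the driver
of the observed ghosting — propagate to the image.

**SNR** is mean(signal ROI) / (SD(air background)/0.655), the Rayleigh
correction √(2−π/2) ≈ 0.655 recovering the per-channel noise σ from a
magnitude background.

## ADC fitting

Polarity pairs are combined as √(S₊S₋) per b, then each sufficiently
bright pixel (max-over-b combined signal > 3× a border-frame background
SD) is fit to S(b) = S₀e^(−bD) + A by Levenberg–Marquardt least squares
with analytic Jacobian, cost tolerance 1e-10, initialized at
A₀ = min S, D₀ = log-linear slope of (S−A₀) over the first three
b-values clipped to [1e-5, 1e-2] mm²/s, S₀₀ = S(b_min) − A₀.

The fit is **unconstrained**. This is a deliberate statistical choice,
established by Monte-Carlo at the protocols' SNR: a one-sided A ≥ 0
bound skews the A–D tradeoff and inflates the ROI-mean ADC of shallow
decays (butanol at SNR 20: ≈ +21% with A ≥ 0 vs ≈ +1% unconstrained);
likewise, censoring pixels whose fitted D is negative, or dropping
fits that stall on the model's degenerate ridge (D → 0, S₀ → ∞,
A → −∞, the curve collapsing to a line in b), truncates the estimator
one-sidedly and re-introduces a +6–8% bias. The pipeline therefore
keeps signed D in the map, records ridge stops as "no resolvable
decay" (D ≈ 0), and flags invalid only non-finite results and
|D| ≥ 0.1 mm²/s (a symmetric runaway window far above free water).
ADC is stored in mm²/s and reported in 10⁻³ mm²/s.

Residual known bias: magnitude noise enters the data in quadrature
(E[M] ≈ √(s²+σ²)) while A is additive, so ROI means acquire an upward
bias that grows as SNR falls — measured through the full pipeline at
compartment SNR 20: water (the fastest decay, whose high-b points sit
at the noise floor) ≈ +20%, tumor ≈ +6%, butanol ≈ +3%; at SNR 150 the
water bias is ≈ +1.6%. The bias shrinks monotonically as noise
vanishes (tested), and a free A still beats A fixed at zero (tested).
A Rician-likelihood fit would reduce it further but is out of scope
here: the offset model is the procedure under study.

ROI statistics pool the ADC map over ROI ∩ validity mask across slices
(mean, sample SD, pixel count). ROI masks come from the phantom label
map eroded by 2 pixels to avoid partial-volume/ringing edges.

## Repeatability statistics

For n paired test–retest values with ΔD = test − retest and pair mean
m: SD_ws = √(Σ ΔD²/2n), CV_ws = √(Σ (ΔD/m)²/2n), RC = 1.96√2·SD_ws.
The unrounded 1.96√2 = 2.7718… is used internally; "2.77" is display
rounding. Bland-Altman limits are bias ± RC (the repeatability
convention, not the classical ±1.96·SD of differences — a documented
divergence). Density curves use a Gaussian KDE with Silverman's
bandwidth. Cross-protocol association is ordinary least squares with
R²; no GEE/GLM inference is provided.

A summary-statistics helper reconstructs Σ ΔD² = (n−1)·SD² + n·mean²
from printed ΔD summaries (sample SD assumed — the reading that
reproduces all six published SD_ws values at two decimals; one RC entry
is reproducible only from the already-rounded SD_ws, so RC is checked
to one unit in the last printed digit).

## Virtual cohort

Each virtual subject scales every compartment diffusivity by a
Gaussian factor (SD 0.17 — placing the tumor between-subject SD in the
observed 0.19–0.29×10⁻³ band); each session applies a further 7.5%
jitter standing in for physiological drift between test and retest,
chosen so the tumor within-subject CV lands near 9% on top of the
noise contribution. Noise is calibrated per protocol so the water tube
reaches a target SNR (default 20) in the lowest-b image, via two short
calibration reconstructions (one noiseless, one noise-only). Subjects,
sessions and noise draw their seeds from one `SeedSequence`, so the
entire cohort is reproducible from a single integer; a noiseless,
motion-free, jitter-free cohort yields ΔD = 0 and SD_ws = 0 for every
tissue (tested).

## Problem sizes

Tests and the acceptance script run the radial protocol at its native
64×101 size; recovery checks use 3 seeds (water, SNR 150 — the
low-noise regime), 8 seeds (tumor, SNR 20) and 16 seeds (butanol,
SNR 20; its 16-pixel ROI gives ≈ 9% per-seed CV, so more seeds are
averaged). The noiseless-cohort property runs 10 subjects at a reduced
48×75 radial size. These sizes keep the whole suite at desk scale
while leaving the acquisitions at the protocols' true geometry wherever
a number is compared against the study's values.

## What the generator does and does not emulate

Emulated: the two trajectories' sampling geometry and timing, gated and
free-breathing schedules, polarity pairs, Rician noise at protocol SNR,
shot-to-shot phase errors and their interleave ghosts, butanol
off-resonance corruption, and the direction and rough magnitude of
motion-elevated ADC. Not emulated: anatomical realism and elastic
motion, through-plane effects, eddy currents, gradient nonlinearity,
coil sensitivities, T1/T2 contrast, perfusion (IVIM), vendor EPI
phase-correction details, and scanner-specific trajectory errors.
Passing tests therefore validate the processing chain and its
statistics under the stated physics, not the biology of real animals.
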