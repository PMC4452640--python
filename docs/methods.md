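# Methods

This note documents the models implemented in `gliomri`, the assumptions
behind them, the phantom that stands in for animal data, and the design
choices made where the design was genuinely open.

## Study design being emulated

Four groups of rats — male/female × tumour/sham, n = 8 per group for
imaging and n = 5 for indirect calorimetry — with three quantitative MR
modalities per animal and ROI statistics in the tumour core, the
contrast-enhancing periphery, and (for perfusion) the whole tumour,
against a contralateral healthy reference region. Group effects are
expressed as %Δ = (glioma − sham)/sham × 100 and tested with Welch's
unpaired two-tailed t test; values are reported mean ± SEM.

## Magnetization transfer

MTR(%) = (S0 − S_MT)/S0 × 100 per voxel. The only numerical subtlety is
the division guard: voxels with S0 below max(ε, 10⁻³ × median brain S0)
are flagged invalid in the map's validity mask rather than zeroed, and
negative MTR values under noise are kept unclipped so ROI means stay
unbiased. The MT pulse-train settings (bandwidth, power, offset) are
carried as metadata only; no quantitative-MT (pool-size) modelling is
attempted.

## Diffusion tensor

The Stejskal–Tanner log-linear system is solved per voxel by ordinary
least squares: row i of the design matrix is
[−b·gx², −b·gy², −b·gz², −2b·gx·gy, −2b·gx·gz, −2b·gy·gz, 1] acting on
(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0). Choices:

- **Plain OLS on log-signals**, not weighted or nonlinear LS: the
  reference analysis is a plain pixel-by-pixel fit; at the SNRs of
  interest the difference is far below the between-subject spread.
- **Both shells (b = 300 and 1400 s/mm²) enter one joint fit**; no
  per-shell ADC.
- **Non-positive signals** make the log undefined; the voxel is flagged
  invalid rather than epsilon-substituted (which would bias the tensor).
- **Negative eigenvalues** of the fitted tensor are clamped to zero and
  the voxel recorded as clamped.
- **Direction set**: vendors rarely publish their tables, so the default
  seven directions are the six (±1,±1,0)-family unit vectors plus
  (1,1,1)/√3, written into the scheme file; the design matrix has full
  rank 7 for this set and any user-supplied set is accepted (a
  rank-deficient one is rejected with a message).
- FA uses the standard normalized form √(3/2)·‖λ − MD‖/‖λ‖ ∈ [0, 1];
  a non-normalized variant (`printed_variant`) is available for
  comparison only and is never used in the pipeline.

Diffusivities are in μm²/s, so b·D carries a factor 10⁻⁶.

## DSC perfusion

Signal is converted to concentration as C(t) = −ln(S/S_base)/TE with
ΔR2* taken linear in concentration and unit proportionality — without an
arterial input function there is no absolute calibration, so all outputs
are arbitrary units, reported relative to a healthy reference region
(which also makes them invariant to global intensity scaling). The
baseline is every frame before the injection time minus one guard frame.

The first pass is modelled as a gamma-variate
C(t) = K(t−t0)^α e^{−(t−t0)/β}, fitted on frames up to 150% of the
return-to-20%-of-peak time (recirculation exclusion, configurable).
Summaries use the closed forms CBV = Kβ^{α+1}Γ(α+1) and MTT = β(α+1);
**MTT is defined relative to the arrival time t0**, making it a pure
shape property of the passage rather than arrival delay, and
CBF = CBV/MTT by the central-volume relation since no AIF deconvolution
is possible. A consequence worth stating: any external CBV/CBF/MTT
triple that does not satisfy the central-volume relation cannot be
reproduced simultaneously — the pipeline's CBF is always CBV/MTT. The
phantom's effect table is exactly such a case: its CBV and MTT cells are
reproduced to numerical precision and its CBF cells are superseded by
CBV/MTT (its sham CBV and CBF rows are bitwise identical, suggesting a
transcription artifact in the original tabulation).

Two fitting routes exist and are cross-checked against each other in the
tests:

- `fit_gamma_variate`: the reference single-curve fitter — scipy bounded
  nonlinear least squares over (K, α, β, t0), initialized from the peak
  and a log-linearized pre-fit; non-convergence and flat curves return a
  flagged result, never an exception.
- `perfusion_maps`: whole-map fitting, numpy-vectorized across voxels.
  For a fixed arrival time the log-domain model is linear in
  (ln K, α, 1/β), so each voxel's t0 is refined by a golden-section
  search (the bracket is the frame interval preceding the first
  above-threshold frame) around batched 3×3 normal-equation solves, then
  (K, α, β) are polished by a batched Gauss–Newton with Levenberg
  damping in concentration space. The arrival time stays at the
  profile-search estimate during the polish; under noise this leaves a
  small systematic difference (a few percent) against the free-t0
  reference fitter, which the cross-check test tolerates explicitly.
  On noiseless data the route is exact to ≈ 1e−9.

The pipeline fits the bolus model over the analysed regions
(tumour + reference) by default and over the whole brain on request
(`dsc_fit="brain"`, also the CLI behaviour) — the maps are identical
voxel-wise; the restriction only avoids fitting voxels nothing reads.
Perfusion is summarized over the whole tumour only, never split into
core/periphery: the acquisition is too coarse for that distinction.

## Group statistics

- `roi_summary` averages valid voxels only and counts exclusions; more
  than 1% flagged voxels in an ROI logs a warning.
- `percent_change` has two aggregation modes because published group
  deltas are not always consistent with the ratio of published group
  means: **group-mean** (ratio of means, first-order error propagation
  for the SEM; the default) and **per-subject** (each glioma subject
  against the sham mean, then averaged). Neither is asserted to be "the"
  original computation; the default is the one that reproduces most
  published deltas.
- `welch_test` works from (mean, SEM, n) summaries or raw values; the
  two coincide exactly when the summaries derive from the values.
  Degenerate zero-variance pairs (possible only in deterministic
  simulations) yield NaN statistics in reports rather than an error.
- No multiple-testing correction by default (matching the original
  analysis); Holm adjustment is available behind a flag.
- RER records are averaged per subject within light and dark bins; the
  light schedule is 12 h/12 h starting in light.

## The phantom

Ground truth is piecewise constant: background brain carries the sham
values of the matching sex, core/periphery the group's tabulated values,
and perfusion quantities live on the relative scale (background = 1).
Geometry: 128 × 128 × 5 grid, 273 μm in-plane, 1.5 mm slices; the
tumour is a 2.78 mm-radius sphere (≈ 88 mm³ voxelized, inside the
75–100 mm³ range at which scanning was triggered) centred off-midline,
with a 2-voxel periphery ring and a mirrored contralateral reference
region; the brain is a 14 mm-radius cylinder.

- **Diffusion truth**: an axially symmetric (prolate) tensor field with
  eigenvalues (MD + 2d, MD − d, MD − d), d = MD·FA/√(3 − 2FA²), which
  realizes any (MD, FA) with FA ∈ [0, 1) at non-negative eigenvalues;
  orientation is uniform (z) by default and immaterial to the
  rotation-invariant MD/FA.
- **DSC truth**: per-voxel gamma parameters with the shape α = 2 held at
  the reference value, β scaling with relative MTT (reference
  MTT = 3.6 s, a typical first-pass width) and K absorbing relative CBV;
  arrival at the 10 s injection time; S_base = 1000, TE = 7.1 ms,
  TR = 250 ms, 150 frames.
- **Noise**: Rician for magnitude images (magnitude of a complex
  Gaussian pair), SNR defined as noiseless signal over the Gaussian σ;
  Gaussian on the DSC signal when configured. All noise is seeded.
- **Cohorts**: subject region means are Normal(group mean, SD) with
  SD = SEM·√8 by default — only SEMs are tabulated, so the population SD
  is reconstructed from them; FA draws are clipped to [0, 0.999] and
  positive quantities floored at 10⁻⁶.
- **RER**: a cosine profile phased so its light- and dark-phase means
  equal the configured day/night levels (the π/2 amplitude factor
  compensates the 2/π half-lobe mean of a cosine), plus Gaussian bin
  noise and a small multiplicative subject effect. Sham levels default
  to 0.88 (light) and 0.97 (dark) — rats feed in the dark, raising
  carbohydrate oxidation — with tumour groups shifted down by
  sex-specific percentages (−4.85/−4.11 male, −1.22/−1.99 female,
  day/night).

What the phantom does *not* emulate — and hence what passing tests do
not show about real data: anatomy (piecewise-constant regions, not
tissue heterogeneity), partial-volume and registration effects, motion
and eddy currents, B0/B1 inhomogeneity, bolus dispersion and leakage,
per-voxel biological variability within an ROI. The round-trip results
validate the estimators and the statistics, not the acquisition physics.

## Problem sizes and determinism

Everything is driven by integer seeds through `numpy.random.default_rng`;
identical arguments and seed give bit-identical outputs, and pipeline
runs write a provenance JSON (versions, seed, config hash) sufficient to
reproduce them. The bundled analyses use a deterministic
2-subjects-per-group cohort for the exactness check, the study's
8 per group for the stochastic group comparison, 5 per group × 60 h for
the metabolic records and 10,000 replicates for the type-I calibration —
sizes chosen to match the emulated study where it states them and to
keep Monte-Carlo error well below the effects of interest elsewhere.

## Known limitations

- The gamma-variate map fitter fixes t0 after the profile search; heavy
  noise or delayed/dispersed boluses would benefit from joint t0
  refinement.
- CBF is structurally CBV/MTT (no AIF); absolute haemodynamics are out
  of reach by design.
- The OLS tensor fit is unweighted; a WLS option would improve
  efficiency at low SNR.
- ROI masks are shared across subjects (one geometry per cohort);
  per-subject anatomical variation is not modelled.
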