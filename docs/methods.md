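# Methods

## Scope and model

`serstax` implements a forward-predictive chemical-taxonomy pipeline for
surface-enhanced Raman (SERS) spectra of epimeric cerebrosides captured by a
4-mercaptophenylboronic acid (4-MPBA) reporter. A spectrum is reduced to 19
fitted peaks × 5 attributes (position, apex intensity, FWHM, skew,
Gaussian/Lorentzian mixing fraction η) and those 95 features feed a
five-level cascade:

1. **RF-C1** blank vs epimer (was anything captured?)
2. **RF-C2** monosaccharide vs cerebroside
3. **RF-C3** saturated vs unsaturated ceramide
4. **RF-C4** glucosyl vs galactosyl hexose
5. **SVM-R 5.1/5.2** ceramide chain length, one regressor per hexose

Each stage answers a conditional question, so each sub-model trains on the
label-filtered subset along its routing path (stage 2 never sees blanks;
stages 3–4 and the regressors train on cerebrosides only). An executive
routine assembles the per-stage decisions into a nomenclature string
(`GlcCer8`, `GalCer24:1`, …); a majority-voting consensus aggregates
replicate spectra. Because every level is a *structural* question rather
than a class label, a cerebroside class entirely absent from training can
still be named — forward prediction — by composing the per-level answers.

Separate support-vector regressions quantify concentration: per-analyte
models regress log₁₀ molarity over seven decades (1e-4…1e-10 M), and a
binary-mixture model regresses the GalCer24:1 mol fraction at a fixed
100 µM total, with the GlcCer24:1 share derived by complement so the pair
always sums to the total.

## Preprocessing

Baseline estimation uses airPLS: an order-2 Whittaker smoother whose
fidelity weights are driven to zero wherever the signal exceeds the current
baseline, with the weight update `w_i = exp(t·|d_i|/|d|₁)` on negative
residuals and termination when `|d|₁ < ratio·|y|₁`. Defaults λ = 1e5,
30 iterations, ratio = 1e-3; λ trades baseline stiffness against peak
erosion and should be increased for very narrow peaks (the test suite's
baseline-recovery oracle uses λ = 5e5 for a 10-point-wide peak). After
baseline subtraction, intensities are min–max normalized (max = 1) and
linearly resampled onto the canonical 1200-point grid over 400–1800 cm⁻¹.
The order — baseline, normalize, regrid — keeps measured samples intact
while the baseline is fitted.

## Peak model and fitting

Each peak is a skewed pseudo-Voigt: `V(x) = A·[η·L + (1−η)·G]` with
side-dependent width `w(x) = fwhm·(1±skew)`, so `skew = 0` means symmetric
and the five attributes remain independent. Intensity is the fitted apex
height (the diagnostic ratios such as I₁₃₃₀/I₁₅₆₇ are height ratios).
Fitting is bounded nonlinear least squares of the 19-component sum; seeds
whose windows overlap are fitted jointly as a cluster, and an optional
second pass refits each cluster against the spectrum minus the others
(removing ~1% tail leakage). Dataset featurization skips that pass by
default: the leakage bias is identical for every spectrum on a shared grid
and cancels in any downstream model, while skipping it halves the cost.
The default 19-band seed table holds the eight chemically assigned reporter
bands (414, 691, 1023, 1330, 1567, 1575, the mobile ~1598 cm⁻¹ a₁ mode,
480) plus eleven filler bands; it is config-replaceable.

Two caveats discovered during development and reflected in the design:
peaks whose amplitude approaches the noise floor have unidentifiable shape
parameters (η and FWHM drift to their bounds), and parameters pinned at a
bound have near-zero variance, which would explode a standardizing scaler.
Regression pipelines therefore use a variance-floored scaler.

## Synthetic data generator

The generator is first-class, tested code: it renders labelled reporter
spectra whose class-dependent deviations encode the five structure→spectrum
correlations (capture drop of the 1330 cm⁻¹ B-OH bend; saturation-dependent
redshift/intensification of the mobile a₁ νCC mode; hexose-dependent
blueshift of the 414 cm⁻¹ band; chain-length-proportional I₁₀₂₃/I₁₅₆₇ for
GlcCer and I₆₉₁/I₁₅₆₇ for GalCer), plus cerebroside marker bands (ceramide
scattering mass) and three class-independent coverage bands that carry the
log-linear concentration response. Ratio targets are specified on the
*measured* scale and converted to amplitudes through a one-off calibration
against the noise-free blank, so neighbouring-peak tails and baseline
shaving do not bias the realized diagnostics.

Noise model (defaults): additive intensity noise σ = 0.01 of the unit
maximum per grid point; centre jitter σ = 0.3 cm⁻¹ per peak; a smooth broad
background removed by preprocessing; within-class scatter of the capture
ratio (σ = 0.003) and of the chain-ratio diagnostics (σ = 0.03, correlated
ρ = 0.8 across the two C–S/ring bands, a shared binding-geometry
fluctuation). Concentration response: the log-linear fraction
`α(c) = (log₁₀c − log₁₀LOD)/(log₁₀c_max − log₁₀LOD)`, applied per rule as
`s_r = 1 − β_r(1 − α)`. The three quant bands have β = 1 (fully
log-linear); capture and marker channels have β < 0.5 so that at the LOD
they still sit past the midpoint between blank and full response; identity
rules have β = 0.02–0.10. Below the LOD every deviation is zero and the
spectrum is flagged blank.

Three generator-design points deserve emphasis because they determine what
passing tests do and do not show:

- **No class fingerprints in non-causal channels.** All cerebrosides share
  one capture ratio, and the coverage bands are class-independent. If the
  capture channel encoded class identity, a forest would learn it as a
  shortcut for *other* stages and leave-one-class-out prediction would
  collapse; and a regressor trained at one concentration would read the
  channel's attenuation as a structural change. Real spectra avoid the
  same failure through wide within-class variance; the generator encodes
  the consequence directly.
- **Within-class scatter on identity diagnostics.** The chain-ratio
  scatter is sized so that no single feature cleanly isolates the one
  unsaturated training class per hexose (which would create pure regions a
  hold-out probe falls into), while keeping per-spectrum chain precision
  near one carbon, consistent with the ±1–2 carbon spreads the method is
  known to produce.
- **Vote balance at the detection limit.** A forest trained at one
  concentration routes a trace-level probe by whichever clean separators
  its trees picked; separators that attenuate to blank level vote wrongly
  at the LOD. The band roster is arranged so persistent separators
  outnumber attenuating ones at every stage (six marker bands + capture +
  a₁ cues vs three coverage bands), which is what makes ≥87% transfer
  accuracy at the LOD attainable rather than trivial or impossible.

What the generator does *not* emulate: multiplicative enhancement-factor
drift between substrate batches, cosmic-ray spikes, wavenumber-axis
miscalibration, analyte impurities, and any physics of electromagnetic or
chemical enhancement. Passing tests show the pipeline's statistical
machinery is sound under the encoded structure→spectrum rules; they do not
certify performance on measured spectra.

## Models and numerical choices

- **Random forests** (all four stages): 1000 trees, √p features per split,
  depth ≤ 10, no splitting of subsets < 5, fixed seed per training.
- **Chain-length regressors**: univariate screening to the 8 features most
  correlated with chain length, then linear-kernel ε-SVR (C = 1, ε = 0.1
  carbons) on variance-floored standardized features. The linear kernel is
  deliberate: the chain response is linear in the band intensities, so it
  extrapolates to unseen chain lengths, whereas an RBF kernel discounts
  the only same-chain training class when it differs in saturation (the
  saturated/unsaturated pair at chain 24). The screening gives exactly
  zero weight to concentration-sensitive bands, keeping chain estimates
  stable when the cascade is probed decades below the training
  concentration. PCA compression was evaluated and rejected for the
  regressors: with 15 components it truncates the chain direction.
- **Quantification / multiplex SVR**: linear kernel, C = 1, ε = 1e-3
  decades (quant) / 1e-4 mol% (multiplex). In the 95-feature space,
  sample-to-sample RBF distances are dominated by noise dimensions, which
  degrades kernel regression by an order of magnitude; a linear model
  projects onto the informative direction. The tiny ε keeps the noise-free
  oracle (R² = 1 within 1e-6) exact.
- **R²** is the squared Pearson correlation between predicted and true
  values on the evaluation split (chemometrics convention).
- **Chain rounding**: nearest integer of the consensus mean — no snapping
  to the catalogue {8, 12, 16, 18, 24}, since the method legitimately
  reports intermediate values like 13 ± 2.
- **Ties** in majority voting resolve toward the class with the larger
  mean probability and are flagged; a stage whose winning probability is
  ≤ 0.5 is flagged low-confidence but never halts routing.
- **Extrapolation flag**: in leave-one-out runs the chain report is
  flagged when the true chain lies outside the matched regressor's
  training range (e.g. GlcCer24:1 held out leaves no 24-carbon
  glucocerebroside); aggregate chain-error statistics cover the
  non-extrapolated hold-outs.
- **Degenerate inputs**: constant vectors are rejected by normalization;
  single-level calibrations raise; zero metric denominators yield flagged
  `None` values, not exceptions.

## Evaluation protocols and problem sizes

Forward prediction removes one cerebroside's 60 spectra, trains on a
stratified 80% subsample of the remaining 780 per iteration, and scores a
held-out spectrum correct only if every applicable stage is correct. The
default protocol runs 100 iterations; the mini protocol (10 iterations) is
used by the acceptance runs, and a 5-fold variant is available. Transfer
evaluation trains once at 1e-4 M without the probe class and scores 10
probe replicates per decade at 1e-5…1e-10 M. Quantification uses a 75/25
stratified split on a 7 × 60 series; the multiplex calibration uses 80/20
on 5 × 60 mixtures with three 10-replicate blind sets. These sizes mirror
the replicate design while keeping a full acceptance run in the tens of
minutes on one core.

## Known limitations

- The identities of all 19 study peaks are not public; the default seed
  table is an explicit stand-in (eight assigned bands + eleven fillers)
  and is replaceable without code changes.
- Whether the study's "intensity" attribute was apex height or integrated
  area is unknown; apex height is used, consistent with its height-ratio
  diagnostics.
- The blind-interpolation accuracy of the multiplex model off the
  calibration grid is limited by mild curvature of the measured feature
  path (a few µM at worst), not by noise.
- Monosaccharide routings terminate at "monosaccharide": the cascade has
  no hexose model for monosaccharides, since stage 4 trains on
  cerebrosides only.
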