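# Methods

`neurodyn` implements a resting-state EEG temporal-dynamics pipeline for
multi-country cohort studies of structural income inequality, together with
a synthetic cohort generator that provides ground truth for every stage.
This note records the models, the defaults and the design choices that were
genuinely open.

## Structural inequality: the Gini coefficient

Country-level inequality is quantified by the Gini coefficient, the
percentage of the area between a population's Lorenz curve and the diagonal
of perfect equality.  With Lorenz coordinates (x_i, y_i) — cumulative
population share against cumulative income share, poorest first — the
coefficient is evaluated by the trapezoid rule

    G = 100 * (1 - sum_i (x_i - x_{i-1}) (y_i + y_{i-1})).

A convenience wrapper builds the Lorenz curve from raw incomes with N equal
population segments.  The trapezoid value agrees with the mean-absolute-
difference form sum|x_i - x_j| / (2 n^2 mu) up to the 1/(2N) discretisation
of the piecewise-linear curve; this is checked by a property test.  G is
scale invariant and lies in [0, 100) for finite non-degenerate samples.

## Signal model of the generator

Each subject's ROI-level EEG is Gaussian noise whose one-sided spectrum is
shaped, in log10-power units, as

    log10 PSD(F) = b - log10(k + F^chi) + sum_p h_p exp(-(F - c_p)^2 / 2 w_p^2),

a Lorentzian aperiodic background (offset b, knee k in Hz^chi, exponent
chi > 0; the reported 1/f slope is a = -chi) plus Gaussian oscillatory
peaks.  Shaping is exact in expectation: Fourier amplitudes are drawn as
complex Gaussians scaled to sqrt(PSD * fs * n / 2), so the Welch estimate of
a generated recording converges to the specified spectrum and every
parameter has a recoverable ground truth.  Defaults: fs = 512 Hz, 300 s,
b = 0, k = 5, chi = 1.5, an alpha peak at a subject-specific frequency
(clipped to 8-12 Hz, height 0.8 log10-units, width 1.2 Hz) and a beta peak
at 20 Hz (height 0.3, width 2.5 Hz) — values in the range typical of
eyes-closed adult resting EEG.  The spectrum is held flat below 0.5 Hz so
ultra-slow drift stays bounded; the analysis band starts at 0.5 Hz.

Two further parameters shape the multivariate structure:

* `noise_mix` (default 0.1) mixes in spectrally white noise, raising
  complexity and flattening the estimated spectrum — the generator's lever
  for planting complexity effects;
* `roi_coupling` g (default 0.35) mixes each ROI with its two ring
  neighbours, x_i = (s_i + g s_{i-1} + g s_{i+1}) / sqrt(1 + 2 g^2).
  Ring mixing was chosen over a single shared latent source deliberately:
  a global source is explained away by conditioning on the remaining ROIs,
  so conditional-mutual-information metrics would not respond to it,
  whereas direct neighbour links survive full partialization.

Artifact epochs (a configurable fraction of 1-s segments) are overwritten
with one of the four data-quality failure modes — large-amplitude bursts,
flatlines, high-frequency noise, decorrelated channels — chosen uniformly
per bad epoch.

## Cohort generator and planted effects

The default cohort emulates ten countries spanning the global south and
north with the sample sizes, Gini values, GDP and demographic distributions
of the emulated multi-centre study (1394 subjects at full scale; a
`subjects_scale` factor shrinks it proportionally).  `EffectSpec` plants
standardized effects of Gini (and age, sex, education, MMSE) on the
generating parameters.  The default directions follow the study's findings:
per SD of Gini the aperiodic slope falls by 0.35 (the exponent rises), the
offset falls by 0.25, alpha and beta peak heights fall by 0.25 and 0.12
log10-units, the white-noise mixture falls by 0.04 (lower complexity), and
the ring coupling rises by 0.10 (higher network integration).  Between-
subject jitter (SDs 0.12 on chi, 0.10 on b, 0.08/0.05 on peak heights,
0.02 on the mixture, 0.04 on coupling) keeps parameter-level correlations
with Gini around 0.9; after signal synthesis and estimation noise the
outcome-level associations are weaker, which is the regime the inference
layer is tested in.  The true parameters are recorded in the cohort table
(`*_true` columns) for recovery tests.  A null spec (all effects zero) is
constructible for calibration.

## Standardization

Recordings are band-pass filtered 0.5-40 Hz by a 4th-order Butterworth
applied forward and backward (`sosfiltfilt`), i.e. an 8th-order zero-phase
net magnitude response; resampled to 512 Hz by the polyphase method
(resampling precedes filtering unless the input is at >= 1024 Hz); truncated
to the first 300 s; and z-scored per channel, with per-centre bookkeeping.
Constant channels cannot be z-scored and are flagged instead.  Two
consequences of this realization are documented because they are testable:
a 50 Hz tone is attenuated to ~14% amplitude (the exact value follows from
the filter's |H|^2 zero-phase response, exposed as
`preprocess.filtfilt_power_response`), and idempotence of re-standardization
holds to 1% only for content inside roughly 1-25 Hz, away from the filter
edges.

Because the filter also shades the edges of the analysis band itself
(gain 0.25 at exactly 0.5 and 40 Hz), the feature-extraction stage divides
the Welch PSD by the known filter response before spectral parameterization.
Without this compensation the knee/exponent fit absorbs the edge rolloff
and subject-level slope differences are masked.

## Spectral analysis

PSD and normalized PSD (nPSD, summing to 1 over 0.5-40 Hz) are estimated by
Welch's method with 1-s Hanning windows, 50% overlap, zero-padded to a 2-s
analysis window (0.5-Hz grid).  Band powers are reported as the mean nPSD in
the band ("equivalent percent power") and the band's percentage of total
nPSD ("relative power density"), over the canonical scheme (delta 1.5-6,
theta 6.5-8, alpha1 8.5-10, alpha2 10.5-12, beta1 12.5-18, beta2 18.5-21,
beta3 21.5-30, gamma 30-40 Hz; intervals closed-left half-open on the grid,
the top band closed) and the subject-specific scheme anchored at two
landmarks: the individual alpha frequency (IAF, maximum nPSD in 7.5-12.5 Hz)
and the theta/alpha transition (TF, minimum nPSD in 4-8 Hz below the IAF),
giving delta [TF-4, TF-2], theta [TF-2, TF], alpha_low [TF, IAF],
alpha_high [IAF, IAF+2], with beta/gamma canonical.  The landmark search
windows are this package's choices; a landmark falling on a window edge is
not a local extremum, and the profile then falls back to IAF 10 Hz / TF 6 Hz
with a flag.

The aperiodic component is fitted in log10 space by an iterative procedure:
a robust initial Lorentzian fit (refit on the 75% of bins with the smallest
residuals, which removes the upward pull of oscillatory peaks); Gaussian
peaks fitted to the residual, largest first, while the maximum residual
exceeds 2 SD (at most 6 peaks, widths bounded to 0.5-12 Hz); and a final
Lorentzian refit of the peak-subtracted spectrum.  Bounds: chi in [0, 8],
k in [0, 1e4], offset in [-20, 20]; knee mode is always on.  Log-space R^2
is always reported; non-convergence yields NaN parameters with a flag.  The
knee and exponent trade off along a flat likelihood valley when the band is
short — recovery tests therefore check the median error over a parameter
grid rather than worst cases.

## Complexity metrics

Four per-ROI metrics on the full standardized series: Higuchi fractal
dimension (kmax = 8, the EEG-standard choice; slope of log mean curve
length against log 1/k), permutation entropy (Bandt-Pompe ordinal patterns,
order 3, delay 1, natural log, normalized by ln 3!, ties broken by temporal
order), Wiener entropy (spectral flatness: geometric over arithmetic mean
of the Welch PSD bins in 0.5-40 Hz, zero bins floored at 1e-30), and
spectral structure variability (SSV), defined here — no published formula
exists — as the mean cosine distance between unit-norm magnitude spectra of
consecutive 2-s windows at 50% overlap.

Because both extremes of these metrics are atypical (regular low-information
signals at the bottom, noise-like signals at the top), subject-level values
are mapped to a uniform complexity scale: z-scored across the pooled sample
(per metric and ROI), with z-scores above +1.2 sign-reversed so the
mid-range is high.  The fold threshold 1.2 SD is the published convention;
pooling across the whole sample rather than per centre is this package's
reading.  Folding is idempotent and bounds the folded maximum at +1.2.

## Quality index

Each 1-s epoch of the z-scored recording is tested against four criteria:
(i) non-finite samples or a constant channel; (ii) any |z| > 5 or
peak-to-peak < 1e-6 z-units; (iii) 25-40 Hz power exceeding 50% of
0.5-40 Hz power on any channel; (iv) more than 25% of channels whose best
absolute correlation with every other channel is below 0.2.  The numeric
thresholds are this package's calibration (the criteria are published
without numbers) and are config-overridable.  OQD is the percentage of
epochs passing all criteria, binned excellent (>= 90), good (>= 80), poor
(>= 60), bad (< 60).  Quality is reported and used as a covariate; no
epochs are dropped.

## Connectivity

ROI series are rank-normalized to standard-normal margins (Gaussian copula:
ranks r -> Phi^{-1}((r - 0.5)/n)), after which information quantities have
closed Gaussian forms in nats: MI = -1/2 ln(1 - rho^2) pairwise; CMI from
partial correlations out of the inverse of the Ledoit-Wolf-shrunk
correlation matrix, conditioning each pair on all remaining ROIs (for two
ROIs the conditioning set is empty and CMI = MI); and the O-information
Omega = (d-2) H(X) + sum_i [H(X_i) - H(X_{-i})] from log-determinants,
positive for redundancy-dominated systems and negative for synergy.  A
per-edge O-information matrix (mean Omega over the triplets containing each
pair, negative edges clipped to zero with a flag) is an artifact
construction that lets the same graph metrics run on all three matrices.

Graph metrics on max-rescaled weights: global efficiency (mean inverse
Dijkstra path length with lengths 1/w), weighted transitivity
(geometric-mean triangle form), density (mean off-diagonal weight), and
small-worldness sigma = (C/C_rand)/(L/L_rand) on the graph binarized at 30%
proportional density against 10 degree-preserving rewired null graphs
(seeded); sigma's null model is defined for binary graphs, hence the
binarization.  Metrics are broadband; frequency-resolved connectivity is
out of scope.

## Inference layer

The analytical space is reduced by two-sided sign-flipping permutation
tests of each ROI-metric mean against zero (default 5000 randomisations,
p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)) with Benjamini-Hochberg
step-up FDR control across ROIs.  Hierarchical OLS regressions use
z-scored continuous predictors (sex coded female = 1), listwise deletion,
and report per-feature estimates/t/p, R^2, Cohen's f^2 = R^2/(1 - R^2), the
model F and p; interactions (gini x age) are products of standardized
mains.  Classification binarises each outcome at its median (ties to class
0), draws k = 10 stratified 80/20 splits, trains an XGBoost classifier per
split (100 trees, depth 3, learning rate 0.1 — unpublished in the source,
fixed here and configurable) and reports AUC/accuracy/precision/recall/F1
per repeat with gain importances averaged and normalized to sum to one.

## Problem sizes and what the tests show

The test suite runs the full pipeline on scaled-down cohorts: the
planted-effect check uses ~400 subjects with 60-s recordings and verifies
that every planted effect direction (lower complexity, slope, offset,
alpha/beta power; higher CMI global efficiency under higher Gini) survives
signal synthesis, standardization, feature estimation and regression, and
that Gini outranks the demographic predictors in classifier importance.
Reproducibility is checked by hashing the feature table of a 100-subject
run twice under one seed.  Calibration checks (permutation-test type-I
rate, FDR against the step-up definition, chance-level classification of
null cohorts) use reduced randomisation counts (500) to keep runtimes
reasonable; the estimators default to the published 5000.

The generator produces stationary Gaussian signals with exact spectral
ground truth.  It does not emulate nonstationary oscillatory bursting,
non-Gaussian amplitude distributions, volume-conduction leakage, or
realistic artifact morphologies beyond the four failure modes.  Passing
tests therefore demonstrate that the estimators recover what they claim to
estimate and that the inference layer is calibrated — not that real
recordings satisfy the model.  Real-data coefficient values and AUCs are
out of scope; only directions, effect-size identities and calibration
properties are asserted.

## Known limitations

* The knee/exponent degeneracy of the Lorentzian fit over a 0.5-40 Hz band
  is intrinsic; knee estimates are the least stable parameter.
* The O-information edge matrix and the CMI conditioning set are documented
  interpretations, not published formulas.
* The 82-region -> 10-ROI default map merges the 90-region AAL parcellation
  (minus bilateral caudate, putamen, pallidum and thalamus) into five lobar
  ROIs per hemisphere; the original merging table is not public.
* EDF support is read-only.
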