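# Methods

This note documents the models, conventions and numerical choices behind
`flimpipe`, in the order data flows through the pipeline.

## Instrument model

The instrument is described by its pulse rate (115 Hz), digitizer rate
(2.5 GS/s raw, 12.5 GS/s after upsampling), decay window (80 ns, holding
a whole number of raw samples), excitation-spot diameter (0.5 mm), and a
Gaussian *system* impulse response. The system response is the
convolution of the excitation pulse (< 60 ps FWHM) with the detection
chain's impulse response (APD + transimpedance amplifier + digitizer
front end), modeled as a Gaussian of 0.8 ns FWHM by default. The detector
term matters twice: physically, it is what actually band-limits the
recorded waveform so that 2.5 GS/s sampling is adequate; numerically, it
is what makes the digitize → upsample → deconvolve chain self-consistent.
The pulse arrives 8 ns into the window, leaving a pre-pulse baseline
segment for noise estimation.

The Nyquist scanning rule exposed by the model is
`0.5 × pulse_rate × lateral_resolution` = 28.75 mm/s at the defaults:
hand scanning slower than this oversamples tissue along the path.

## Synthetic cohorts

The generator emulates the clinical study design: `n_mixed` patients
(default 13) carry adjoining cancer and healthy regions scanned
serpentine-fashion at 30 mm/s, and `n_healthy_only` patients (default 2)
carry healthy tissue only. Every point receives ground-truth per-channel
average lifetimes and intensity ratios drawn from a tissue model with
three variance tiers: a per-subject random offset (shared across tissue
classes, emulating animal-to-animal heterogeneity), within-subject
Gaussian scatter, and — optionally — a healthy-subregion shift emulating
gingiva-versus-mucosa heterogeneity in the PpIX band (off by default; its
magnitude has no literature anchor).

**Effect-size calibration.** Cohen's *d* in the downstream screen is the
tissue mean difference over the mixed model's residual SD. Because both
classes share one within-subject SD σ_w and the class shift is constant
across subjects, setting the cancer mean to healthy mean + *d*·σ_w makes
the target exact in expectation; the calibration is solved analytically,
never tuned. The in vivo preset calibrates channel-1/-2 lifetimes to
*d* = −0.74 / −0.65 and the channel-3 intensity ratio to +0.61; the ex
vivo preset calibrates the channel-2 lifetime to −0.83 and the channel-3
intensity ratio to +1.0, with a depressed channel-1 intensity share.
Intensity ratios are parameterized by the channel-3 fraction r₃ and the
channel-1 share q of the remainder, so the three ratios sum to one by
construction and r₃'s calibration is exact.

**Waveforms.** Each channel's decay is a fixed-shape two-component
mixture (amplitudes 0.6/0.4 at relative lifetimes 0.5/1.291, chosen so
the amplitude-weighted first moment is exactly the point's true
lifetime). The forward model is the *discrete* convolution of the
digitized system IRF with the sampled decay on the fine (12.5 GS/s)
grid, decimated to the 2.5 GS/s record. This convention was chosen over
sampling the analytic continuous convolution because the decay's jump at
t = 0 makes the continuous and discrete models differ at the percent
level, which an expansion fit cannot absorb; with the discrete
convention, noiseless round trips through preprocessing and
deconvolution close to interpolation accuracy (≈0.2%). Channel peak
amplitudes scale as (intensity ratio / lifetime) × gain so that the
*integrated*, gain-corrected channel intensity fraction — what the
pipeline measures — equals the true intensity ratio.

**Noise and background.** A fiber-fluorescence template (1.8 ns decay,
gain-scaled, peak 10% of a reference signal) contaminates every record
and is what background subtraction removes. Additive white Gaussian
noise is scaled to a target peak-SNR of 55 dB (the post-averaging
precision regime of pulse-sampled FLIm systems, giving ≈0.1–0.2 ns
per-point lifetime precision) and amplified beyond a gain knee of 300 to
emulate excess detector noise at high gain. At SNRs tens of dB lower, a
first-moment estimate over an 80 ns window is noise-dominated no matter
the estimator; the SNR default is a property of the instrument being
emulated, not a tuning knob.

What the generator does **not** emulate: probe-angle and contact
variation, motion blur, photobleaching, tissue optical-property
gradients, registration error between scan and histology (labels are
exact by construction), and non-Gaussian detector noise. Passing tests
therefore demonstrate correctness of the *analysis*, not robustness to
every clinical artifact.

## Preprocessing

Background subtraction is exact elementwise subtraction of a per-channel
(optionally per-point, gain-scaled) template. Upsampling is polyphase
band-limited interpolation (Kaiser β = 12, linear-extension padding;
passband ripple ≈1e−6, edge transients confined to one filter length).
SNR is peak amplitude over the SD of the pre-pulse baseline (first
twelfth of the window), in dB; the keep floor defaults to 20 dB. Gain
keep-ranges default to (15, 300) for channel 1 and < 800 for channels 2
and 3, and can be re-derived by the iterative calibration: bin gains in
steps of 50 over (50, 1000), track the lifetime SD per bin, and place
the threshold at the last bin before the SD first exceeds twice the
median SD of the preceding bins ("increases significantly" made
reproducible; the factor is exposed).

## Decay features

The discrete Laguerre basis is generated by the standard first-order
all-pass cascade and then orthonormalized on the finite sample grid by a
sign-fixed QR factorization. For well-contained parameters the QR step
is a no-op to ~1e−6; for slow bases on short windows it restores exact
grid orthonormality without changing the span (what deconvolution uses).
Deconvolution solves min‖y − IRF∗(Bc)‖² by a cached pseudo-inverse, so a
full scan is one matrix product. The expansion order is 12 per channel
(36 coefficients per point); α is fixed per channel at (0.955, 0.955,
0.966), chosen once by round-trip residual and moment bias/variance on
calibration decays spanning each channel's lifetime range
(`select_alpha` reproduces the procedure). The fitted decay is clipped
at zero before moment/phasor computation (raw coefficients are kept as
features).

The average lifetime is the left-Riemann first moment
τ = Σₙ tₙ h(n)/Σₙ h(n). Two systematic terms are documented rather than
hidden: a −dt/2 (−0.04 ns) quadrature offset relative to the continuous
moment, and window truncation for the slowest PpIX-band decays (an 80 ns
window holds < 7 e-folds of a 10 ns decay, costing ≈0.1 ns of moment).
Phasors use the same discrete sums at harmonics {1, 2} of the window
fundamental (12.5 MHz for 80 ns); mono-exponential phasors land on the
universal semicircle up to O(ω·dt) quadrature terms (≈3e−3 at the
default grid). Channel intensity for the intensity ratios is the
integrated waveform area referred to detector gain 100, so ratios
compare photon flux rather than amplification.

Invalid channels (non-positive intensity, failed deconvolution)
propagate NaN features plus flags; such points are dropped as missing
values, never zero-filled.

## Co-registration

Labels live on an integer raster (0 unlabeled, 1 healthy, 2 cancer,
3 dysplasia) with mm geometry: origin at the raster corner, pixel
centers, half-open pixel intervals — stated so lookups on generated data
are bit-exact. Points within a buffer (default 0.5 mm ≈ one excitation
spot) of the cancer-healthy interface are excluded as mislabel-prone;
distance is measured between pixel centers via Euclidean distance
transforms. Dysplasia is excluded by default (the analysis is binary and
the class's disposition is genuinely ambiguous); a flag folds it into
non-cancer instead. Out-of-raster points are excluded as unlabeled.

## Weights, transforms, and the univariable screen

Weights are wᵢ = (N/C)/n₍s(i),t(i)₎ with N observations and C populated
subject×tissue cells: weights sum to N, every cell carries equal mass,
mixed subjects split their mass evenly across tissues, and a
healthy-only subject carries exactly half a mixed subject's mass.

Features with weighted |skewness| > 1 are shifted to zero minimum
(left-skewed columns are reflected first) and square-rooted; every
column is then weighted-standardized. All moments use the analysis
weights so over-represented patients do not drive transform decisions.

The univariable model is y = β₀ + β₁·cancer + b_subject + e with
b ~ N(0, τ²) and e ~ N(0, σ²/wᵢ): weights act as residual precisions.
With one random intercept and diagonal weights the REML criterion
reduces, via the Woodbury identity, to per-subject weighted sums; the
variance ratio θ = τ²/σ² is profiled on a log grid plus bounded
refinement (θ = 0 is checked explicitly), and β is GLS at the optimum.
Cohen's d is β₁/σ; p-values are Wald (the smallest screened cohorts have
thousands of points, so z ≈ t). Benjamini-Hochberg adjustment spans all
features screened in one phase; in vivo and ex vivo are adjusted
separately because they are separate analyses.

## Multilevel weighted PCA

For each Laguerre and phasor block per channel: weighted subject means
are computed; the between-subject PCA decomposes the subject-mean matrix
(subjects weighted by their mass, which the weight scheme makes equal
for mixed subjects); the within-subject PCA decomposes pooled deviations
with observation weights as row masses. Weights-as-masses makes the
decomposition invariant to duplicating observations with compensating
weights. Single-tissue subjects are excluded from fitting and scored
with the fitted loadings. Two components per level are retained;
loadings are orthonormal with a largest-entry-positive sign convention.

## Logistic mixed model and backward selection

The multivariable model is logit P(cancer) = x'β + b_subject with
weighted likelihood. For fixed τ² the joint penalized likelihood in
(β, b) is maximized by damped Newton steps using the Schur complement of
the diagonal random-effect block; the marginal likelihood is Laplace-
approximated (the correction is a sum of scalar log terms because the
random effect is an intercept), and τ² is profiled by one-dimensional
bounded optimization. Standard errors come from the fixed-effect block
of the inverse joint Hessian. Tests verify the estimates against a
60-node Gauss-Hermite quadrature oracle (2% contract). Suspected
separation (runaway coefficients or SEs) is flagged, not raised.

Backward selection runs two phases: while any VIF exceeds 10, remove the
single largest-VIF predictor (VIF is computed on the weighted design
directly, so this phase needs no model refits); then, refitting after
each removal, drop the largest-p predictor while any p exceeds 0.05.
Ties break by column order; each step removes exactly one predictor, so
termination is bounded by the predictor count; an audit trail records
every removal with its triggering value. The stopping rule retains
predictors with p ≤ 0.05 (the conventional reading of "removing
predictors with large p-values").

## Classifier

Evaluation is leave-one-patient-out: for each patient carrying both
classes, train on all other patients' points — with the analysis weights
as sample weights, so each patient and tissue contributes equally — and
score the held-out patient (threshold-free AUC plus accuracy/
sensitivity/specificity at probability 0.5). The protocol is the
strictest defensible reading of per-patient evaluation and is
configurable. Model families: a depth-limited decision tree (default)
and LDA (which ignores sample weights — its `fit` does not accept them).
The feature-combination grid search evaluates all 15 non-empty subsets
of {lifetimes, intensity ratios, Laguerre, phasors} under identical
seeds and ranks by mean per-patient AUC. Hyperparameter search
enumerates the finite space in deterministic order (exhaustive within
budget, otherwise a seeded random subset), logging every trial; for the
small spaces used here exhaustive search satisfies the
sequential-search contract. Cohort rollups report mean, SD and median;
a single-patient rollup reports SD 0 with a flag.

## Degenerate inputs and tie-breaks (summary)

Zero waveforms → zero coefficients, flagged; non-positive decay
intensity → NaN lifetime/phasors, flagged; zero-variance columns skip
standardization, flagged; perfect collinearity → VIF = +inf sentinel;
all predictors removed → empty model, flagged; single-class test
patient → excluded from AUC with a reason. All stochastic components
take a single integer seed; fixed seeds give byte-identical cohorts,
tables, rankings and reports.

## Known limitations

- The label rasters on synthetic data are exact; real histology
  co-registration error is not modeled, so exclusion rules are exercised
  geometrically rather than statistically.
- The Laplace approximation can bias τ² at very small cluster counts;
  the Gauss-Hermite contract is verified at 2 subjects, but fixed-effect
  SEs there are approximate.
- The average lifetime inherits a −dt/2 quadrature offset and
  window-truncation bias for decays slower than ≈9 ns (see above); both
  are orders below the tissue contrasts of interest but visible in
  high-precision recovery tests.
- The decision tree is deliberately shallow by default; no calibration
  of predicted probabilities is attempted, and AUC is the primary
  metric.
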