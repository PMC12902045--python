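# flimpipe

**Pulse-sampled fluorescence-lifetime imaging (FLIm) analysis pipeline for
intraoperative cancer / healthy tissue discrimination.**

Fiber-based point-scanning FLIm measures, for every laser pulse, the
nanosecond-scale decay of tissue fluorescence in three spectral channels —
collagen (390/40 nm), NAD(P)H (470/28 nm) and protoporphyrin IX
(629/53 nm) — while a surgeon sweeps the probe across a tumor and its
margin. Because decay *dynamics* (unlike raw intensity) are largely
independent of illumination and probe-tissue distance, lifetime-derived
features can separate neoplastic from healthy oral epithelium in real
time. This package implements the complete analysis chain for such data,
together with a calibrated synthetic-cohort generator that stands in for
clinical scans (which are not publicly available), so every stage is
testable against known ground truth.

The pipeline:

1. **Simulation** (`flimpipe.synthetic`) — cohorts of 15 patients (13 with
   both tissue classes, 2 healthy-only) with per-pulse waveform records:
   two-component exponential decays convolved with the digitized system
   response (60 ps excitation pulse ⊗ 0.8 ns detector response), fiber-
   background contamination, detector-gain scaling, gain-dependent noise,
   2.5 GS/s sampling, 115 Hz serpentine scan paths, and pathology label
   rasters in the same mm coordinate frame. Class separations are
   calibrated **analytically** to requested Cohen's *d* values.
2. **Preprocessing** (`flimpipe.preprocess`) — fiber-background
   subtraction, band-limited 2.5 → 12.5 GS/s upsampling, gain and SNR
   quality filtering, and iterative gain-threshold calibration from the
   lifetime-SD-versus-gain profile.
3. **Features** (`flimpipe.laguerre`, `flimpipe.features`) — per channel:
   Laguerre-expansion deconvolution (h = Σⱼ cⱼ bⱼᵅ, 12 coefficients),
   average lifetime τ = Σₙ tₙ h(n) / Σₙ h(n), phasors
   g = Σ h cos(ωt)/Σh, s = Σ h sin(ωt)/Σh at harmonics {1, 2} of the
   12.5 MHz window fundamental, and gain-corrected intensity ratios
   IRₖ = Iₖ / ΣI — 54 features per point.
4. **Co-registration** (`flimpipe.coregister`) — raster label lookup with
   interface-buffer, unlabeled and dysplasia exclusions.
5. **Statistics** (`flimpipe.weights`, `.transforms`, `.mixedlm`,
   `.screen`, `.mlwpca`, `.logisticmm`, `.selection`) — inverse-cell-count
   analysis weights wᵢ = (N/C)/n₍s,t₎; skew-aware transforms; a weighted
   linear mixed model (REML) per feature giving Cohen's
   *d* = (cancer − healthy mean) / residual SD with Benjamini-Hochberg
   adjustment; multilevel weighted PCA splitting between- and
   within-subject variation; and a weighted logistic mixed model (Laplace)
   pruned by VIF > 10 then p > 0.05 backward selection.
6. **Classification** (`flimpipe.classify`) — leave-one-patient-out
   evaluation, grid search over all 15 feature-group combinations, and
   per-patient ROC/AUC with cohort rollups.

## Worked example

The numbered drivers under `analysis/` run the whole study at demo scale
(15 patients, 600 points per class per phase) and write their tables under
`results/run/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_extract_features.py
python analysis/03_assign_labels.py
python analysis/04_effect_sizes.py
python analysis/05_multivariable_model.py
python analysis/06_classifier.py
```

Representative output (seed 1):

```
[in_vivo] strongest tissue discriminators (Cohen's d, BH-adjusted p):
         feature  cohens_d  p_adjusted magnitude
   phasor_s1_ch1    -0.752    2.75e-34    medium
   lifetime_ch1     -0.733    3.33e-33    medium
[ex_vivo] strongest tissue discriminators:
       ir_ch1       -1.08     2.77e-70    large
       ir_ch3        1.00     2.95e-61    large
[in_vivo] best combo: intensity_ratios+phasors | mean (SD) AUC 0.72 (0.05)
[ex_vivo] best combo: intensity_ratios+phasors | mean (SD) AUC 0.78 (0.04)
```

Reading this: in vivo, the channel-1 (collagen-band) lifetime is shorter in
cancer (*d* ≈ −0.73, a medium-to-large effect), and phasor coordinates —
which encode the same decay — discriminate comparably; ex vivo, the
spectral intensity ratios dominate, with the PpIX-band ratio higher in
cancer (*d* ≈ +1.0). Per-patient leave-one-patient-out AUCs average ≈ 0.72
in vivo and ≈ 0.78 ex vivo. All of these mirror the calibration built into
the generator, which is the point: the pipeline recovers what was planted.

The same run is available as a single command via the CLI:

```bash
flimpipe all --config configs/demo.yaml --out results/demo --seed 1
```

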