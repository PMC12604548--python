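# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `aveffort`. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The effort model and its inference

### Quadratic effort curves

Listening effort (peak pupil dilation, PPD, in mm; frontal midline theta in
dB re baseline) is modelled per outcome as a concave quadratic in centered
SNR, `x = SNR − c` with `c = −6 dB`, the mean of the design
{−12, −8, −4, 0}. Centering makes the linear and quadratic regressors
exactly orthogonal over this design (Σx³ = −216 − 8 + 8 + 216 = 0), which
removes the collinearity that otherwise destabilises the fit. The modality
factor is treatment-coded with auditory-only (AO) as reference, so the
`mod*` coefficients are audiovisual (AV) offsets — a requirement for the
AV vertex formula below to be meaningful. The visual-only (VO) condition is
generated for end-to-end realism but never modelled: it has no SNR
manipulation, so it carries no information about the curve.

Fitting is restricted maximum likelihood (statsmodels `MixedLM`) with a
single random intercept per subject on condition-level data (one aggregated
observation per subject × modality × SNR). The behavioral outcome is the
proportion of keywords correct modelled as a Gaussian LMM without a
quadratic term; its bounded support argues for a binomial GLMM, but the
Gaussian LMM on proportions is the convention this pipeline reproduces, and
the simplification is deliberate. Per-coefficient tests are Wald z tests
from the REML fixed-effect covariance; no Satterthwaite or Kenward–Roger
degree-of-freedom correction is implemented, and the tests are labelled
accordingly. Near-boundary variance components occasionally trip the
default optimizer; the fit retries with L-BFGS and Powell before raising.

### Vertex ("peak SNR") and peak shift

For a concave quadratic the SNR of maximal effort is the vertex:
`Peak_AO = −β_S/(2β_S²)` and
`Peak_AV = −(β_S+β_MS)/(2(β_S²+β_MS²))` on the centered scale; raw-scale
peaks add the centering constant, and the shift `Peak_AO − Peak_AV` is
centering-invariant. A vertex whose quadratic coefficient is non-negative
is a minimum, not a peak, and is flagged.

Uncertainty is propagated by posterior simulation: 1,000 coefficient
vectors are drawn from the multivariate normal centered at the REML
estimates with the fitted fixed-effect covariance (the flat-prior
large-sample posterior approximation; no model refitting), vertices are
computed per draw with the pairing preserved, and the shift draws are
summarised by their mean, a one-sided paired t statistic across draws, the
2.5–97.5 percentile interval, and the fraction of non-positive draws. All
draws are kept by default; an optional concavity filter drops non-concave
draws and reports how many.

Two statistical properties of this construction deserve emphasis:

* **The vertex is a ratio statistic.** When a quadratic-coefficient draw
  comes near zero the vertex explodes, so with poorly resolved curvature
  the shift distribution is heavy-tailed and the percentile interval can
  span tens of dB. For the same reason the *mean over draws* is an
  upward-biased point estimate (the vertex is convex in the curvature
  draw). The package therefore reports the **plug-in shift** — the vertex
  formulas applied to the REML estimates — as its point estimate, with the
  draw mean kept as the summary of the propagated distribution.
* **The draw-level t test is not a calibrated test.** The paired t across
  n posterior draws compares the draw mean to its *Monte-Carlo* standard
  error; its statistic grows like √n with the number of draws and it
  rejects whenever the point estimate is even slightly positive. It is
  implemented because it is part of the procedure this package reproduces,
  but for a calibrated one-sided decision use `p_shift_nonpositive`, the
  posterior probability of a non-positive shift (reject at α = .05 when
  fewer than 5 % of draws are non-positive). The test suite verifies that
  this rule fires in ≤ 10 % of 50 studies simulated with a true shift of
  zero, and that the 95 % percentile interval covers zero there.

## 2. Pupil pipeline

Order: blink detection → interpolation → zero-padding → low-pass →
exclusion → baseline correction → condition averaging → PPD. Choices:

* **Blink detection**: samples beyond 3 SD of the trial mean (mean and SD
  computed once over the whole trial, artifacts included — a single,
  non-iterative pass) are invalidated together with ±150 ms around them;
  pre-existing hardware dropouts stay invalid. A constant trace yields no
  detections; an all-invalid or zero-variance-with-NaN trace is an error.
* **Interpolation**: linear between nearest valid neighbours; leading and
  trailing invalid runs are filled by nearest-valid constant extension
  (linear interpolation is undefined without two anchors). The fraction of
  filled samples is the trial's `interp_fraction`.
* **Low-pass**: fifth-order Butterworth at 3 Hz, applied forward–backward
  (zero-phase) so the PPD latency is not shifted; the effective attenuation
  is the squared single-pass response. The filter runs in float64 — with a
  3 Hz cutoff at 1200 Hz the poles sit close enough to the unit circle
  that float32 recursion loses visible precision — over row blocks of the
  padded trial matrix to bound memory.
* **Exclusion**: trials with `interp_fraction > 0.40` (strictly greater)
  are dropped; subjects with > 40 % dropped trials are removed entirely;
  the report lists both, and an emptied dataset raises with the report
  attached.
* **Padding-aware statistics**: variable-length trials are zero-padded
  into one matrix, but the padding is masked out of condition averages and
  of the PPD search window — a literal max over zero-padded averages would
  bias the PPD toward time ranges where fewer trials contribute.
* **Baseline and PPD**: the 1–2 s post-onset mean is subtracted per trial
  (0–1 s is skipped as startle-contaminated); PPD is the maximum of the
  condition-average trace within 2–7 s. Both windows are configuration
  values; 2–6 s is an equally defensible analysis window and supported via
  `PupilConfig(ppd_window_s=...)`, with 2–7 s as the default.
* **Two eyes**: the on-disk format carries both eyes; ingestion averages
  them where both are valid and uses the valid one otherwise.

## 3. EEG pipeline

Preprocessing: average reference, 0.5 Hz high-pass, 60 Hz low-pass,
48–52 Hz band-stop (fourth-order zero-phase Butterworth each), polyphase
resampling to 256 Hz, epoching 0–7 s from noise onset (onsets without room
for a full epoch are skipped with a warning). ICA-based artifact removal is
a human-in-the-loop step and is out of scope; an amplitude-threshold epoch
rejection can stand in where needed, and the synthetic data are generated
artifact-light.

Time–frequency analysis: complex Morlet wavelets at 3–13 Hz in 0.5 Hz
steps. The cycle schedule is a configurable vector, by default rising
linearly from 3 cycles at 3 Hz to 6.5 at 13 Hz; `wavelet_fwhm` exposes the
envelope width `2√(2 ln 2)·n/(2πf)` so any published time-resolution
figure can be matched exactly (a constant 3-cycle schedule, for reference,
gives 375 ms FWHM at 3 Hz). Single-trial power is baselined by dividing by
the mean power of the 0–2 s window per channel × frequency, then converted
to dB as `10·log₁₀` (power quantities), then averaged over 4–7 Hz,
2–6 s, and AF3/AFz/AF4; per-trial values are averaged within condition.
Samples within two envelope SDs of an epoch edge are flagged as
edge-contaminated and excluded from the baseline mean (convolution edges
would otherwise deflate it — the same behaviour as NaN-padded convolution
edges in common EEG toolboxes).

**dB statistics of the log-then-average recipe.** The log is taken on
single-trial, single-sample power *before* averaging. For a Gaussian
signal, single-sample wavelet power is exponentially distributed, so the
expected dB value sits below the dB of the expected power by
`10γ/ln 10 ≈ 2.51 dB` (γ the Euler–Mascheroni constant), partly offset by
the finite averaging of the baseline window (`≈ +0.3 dB` for a 2 s window
at these wavelet widths; `log_power_bias_db` computes both terms). The
offset is common to all conditions, so it cancels from condition contrasts,
from the fitted SNR coefficients, and from the vertices; only absolute
theta levels carry it.

## 4. The synthetic-data generator

The generator defines the study conditions: 22 subjects × {AO, AV, VO} ×
{−12, −8, −4, 0 dB} × 20 trials, pupil at 1200 Hz, EEG at 1024 Hz over a
64-channel 10-10 montage, trials of 2 s noise/static image + a sentence of
3.87–5.4 s + 2 s post-noise (EEG epochs trimmed to 0–7 s, pupil traces
kept at full variable length). One master seed drives per-subject spawned
random streams, so every table and trace is byte-reproducible.

* **Effort curves**: the default pupil curve uses the group-level
  coefficients this package reproduces (intercept 0.25 mm, linear 0.003,
  quad −0.001, AV offsets 0.05/−0.005/2×10⁻⁴), giving true vertices at
  −4.5 (AO) and −7.25 dB (AV), shift 2.75 dB; `params_with_true_shift`
  adjusts the AV slope offset to plant any desired shift (2.6 dB in the
  recovery experiments). The default theta curve keeps the AO vertex at
  −4.5 dB with the group-level curvature (−0.002 dB/dB²) and a 0.86 dB
  true shift. Subjects carry zero-mean random intercepts (0.03 mm pupil,
  0.3 dB theta), an SRT shift (SD 1.5 dB) that slides both the
  psychometric function and the effort curves along SNR, and a tonic pupil
  size (3.5 ± 0.4 mm).
* **Pupil trials**: tonic level plus a gamma-like dilation kernel
  (`(τ/τ_p)^a e^{a(1−τ/τ_p)}`, unit peak 2.5 s after speech onset, shape
  a = 2 — the trace shape is not prescribed by any source, so the kernel
  is a documented, configurable choice), with amplitude = effort curve +
  subject intercept + trial jitter (SD 0.08 mm), slow drift (SD 0.02 mm,
  < 0.5 Hz), white sensor noise (SD 0.01 mm), and Poisson blinks
  (0.15 /s; 60–180 ms; half missing runs, half ±2 mm excursions). Noise
  magnitudes were chosen once for trial-level realism of sentence-test
  pupillometry; with 20 trials per condition they put the condition-level
  PPD residual near 0.02 mm.
* **EEG trials**: per-channel 1/f background (RMS 10 µV, exponent 1,
  flattened below 1 Hz), plus a theta burst: an independent 1/f
  realisation spectrally truncated to 1–12 Hz *at the background's own
  spectral scale*, multiplied by an envelope that is 1 during 2–6 s (0.15 s
  cosine ramps inside the window) and scaled by gain β per channel. This
  construction makes the in-band active/baseline power ratio exactly
  1 + β² at every in-band frequency, so the planted frontal theta is
  well-defined; β is set from the planted value with the log-recipe offset
  of §3 compensated. Frontal midline channels carry the full planted
  value, Fp/F midline neighbours 0.6 of it, other sites 0.2. Optional
  10 Hz alpha contamination is off by default. The residual absolute
  planting error (envelope-edge smearing plus the approximate baseline
  term) is about −0.25 dB, constant across conditions; the acceptance test
  budgets 0.5 dB for absolute recovery, and contrasts are unaffected.
* **Behavior**: keywords correct ~ Binomial(3, p) with
  `p = logistic(0.6·(SNR − SRT_modality − SRT_subject))`, SRTs −4 dB (AO)
  and −8 dB (AV) so ~50 % recognition coincides with the planted effort
  peaks; VO uses a fixed p = 0.1. Note the 4 dB SRT spacing implies a
  larger average AV recognition benefit than a smaller spacing would; it
  is the generator's stated condition, not a fitted quantity.

**What the generator does not emulate**: subject-specific curve *shapes*
(random slopes/curvatures — only curve position varies), eye-specific
signals or realistic blink kinematics, gaze artifacts, spatially coherent
EEG sources with volume conduction, non-stationary 1/f, EMG/ocular EEG
artifacts needing ICA. Passing recovery tests therefore show the chain is
correct and well-calibrated for this generative family, not that real-data
preprocessing difficulty is solved.

## 5. Problem sizes in tests and the acceptance script

Parameter-recovery and null-calibration experiments run 20 and 50
full-scale pupil studies (21 subjects, default noise). Spectral recovery
uses 200 single-condition trials on an 8-channel montage at 256 Hz —
generation directly at the analysis rate is equivalent here because every
simulated component lives far below either Nyquist frequency. The
acceptance script averages the estimated shift over five replicate
22-subject studies (the single-study estimator is heavy-tailed, §1) and
runs the theta path on a reduced 8-subject × 6-trial × 16-channel study;
the theta shift estimate is reported as computed, with the caveat that the
theta curvature (−0.002 dB/dB²) is near the resolution limit of a study
this size, so that number is intrinsically noisy — matching the very wide
theta intervals the full-scale procedure produces.

## 6. Known limitations

* Wald z tests without small-sample df corrections are mildly liberal at
  21–22 subjects.
* The Gaussian LMM on proportions can predict outside [0, 1].
* The posterior is a normal approximation around the REML estimates; no
  refitting, no prior, no df adjustment (and the percentile interval is
  one possible CI construction among several).
* Absolute theta levels carry the log-recipe offset (§3); only contrasts
  are bias-free, and the generator's compensation of the offset is
  analytic and ~0.25 dB short.
* EDF files are read (via mne) but not written; bulk EEG interchange uses
  float32 arrays with JSON sidecars.
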