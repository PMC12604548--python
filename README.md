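# aveffort

Audiovisual listening-effort analysis: pupillometry, frontal midline theta,
quadratic-SNR mixed models, and posterior-simulation peak-shift inference.

## The scientific problem

Understanding speech in noise takes cognitive effort. Two physiological
markers track that effort: **peak pupil dilation (PPD)** and **frontal
midline theta power** (4–7 Hz EEG over AF3/AFz/AF4). As the signal-to-noise
ratio (SNR) drops, effort first rises, then collapses when the task becomes
hopeless and listeners disengage — an *inverted U* over SNR. Seeing the
talker's face (audiovisual, AV, vs. auditory-only, AO, speech) lowers
cognitive demands, which should slide the whole inverted U toward harder
SNRs. This package implements the full analysis chain needed to test that
prediction — for people running speech-in-noise studies with eye tracking
and EEG, and for anyone who wants to probe the statistical behaviour of the
method on simulated data with known ground truth.

## The model

Effort is modelled as a concave quadratic in centered SNR
(`x = SNR − (−6 dB)`), per outcome (PPD in mm; theta in dB re baseline):

```
y  =  β₀ + β_M·AV + β_S·x + β_MS·AV·x + β_S²·x² + β_MS²·AV·x² + u_subject + ε
```

fitted as a linear mixed model (REML, random intercept per subject,
treatment coding with AO as reference). The SNR of maximal effort is the
vertex of the parabola:

```
Peak_AO = −β_S / (2·β_S²)
Peak_AV = −(β_S + β_MS) / (2·(β_S² + β_MS²))
```

and the **audiovisual peak shift** is `Peak_AO − Peak_AV` (positive when AV
effort peaks at a harder SNR). Uncertainty is propagated by posterior
simulation: coefficient vectors are drawn from `N(β̂, V̂)`, vertices are
computed per draw, and the shift distribution is summarised by its mean,
percentile interval, and the fraction of non-positive draws.

The measurement pipelines feeding those models follow standard practice:
blink rejection at ±3 SD with ±150 ms padding, linear interpolation,
zero-padding, 3 Hz fifth-order zero-phase Butterworth smoothing, >40 %
trial/subject exclusion rules, 1–2 s baseline subtraction, and
within-window (2–7 s) PPD on the pupil side; average reference, 0.5/60 Hz
band limits, 50 Hz band-stop, 256 Hz resampling, Morlet wavelets (3–13 Hz
in 0.5 Hz steps), dB baselining against 0–2 s, and 2–6 s frontal averaging
on the EEG side.

A first-class synthetic-data generator simulates complete studies
(subjects × {AO, AV, VO} × {−12, −8, −4, 0 dB}) with a configurable
planted peak shift, so every stage is testable end to end against known
ground truth. See `docs/methods.md` for the generative model and all
numerical choices.

## Worked example

Simulate a full-scale study with a planted 2.6 dB pupil peak shift, run the
entire pipeline (pupil preprocessing → mixed model → posterior simulation),
and compare against ground truth:

```python
import numpy as np
from aveffort import StudyDesign, StudyParams, simulate_study, recover_shift_end_to_end
from aveffort.curves import DEFAULT_PUPIL_PARAMS, params_with_true_shift

params = StudyParams(pupil_curve=params_with_true_shift(DEFAULT_PUPIL_PARAMS, 2.6))
study = simulate_study(StudyDesign(n_subjects=22), params, seed=2,
                       streams=("behavior", "pupil"))
res = recover_shift_end_to_end(study, "ppd", rng=np.random.default_rng(3))
```

This prints (exact numbers for these seeds):

```
true peak shift:       2.60 dB
estimated peak shift:  2.34 dB (plug-in)
posterior draws:       mean 2.43 dB, 95% CI [1.37, 3.65] dB
P(shift <= 0):         0.000
peak SNRs:             AO -4.78 dB, AV -7.12 dB
```

The estimated AO effort peak sits near −4.5 dB SNR and the AV peak ~2.5 dB
lower: visual speech shifts the point of maximal effort toward harder
SNRs, and essentially no posterior draw puts the shift at or below zero.

The same pipeline is available from the shell:

```
aveffort run-all --seed 2 --out results/run
aveffort simulate / pupil / eeg / fit / peaks   # individual stages
```

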