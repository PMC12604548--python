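"""Synthetic audiovisual speech-in-noise studies with known effort structure.

The generator emulates the experimental design the analysis modules expect:
subjects x modality {AO, AV, VO} x SNR {-12, -8, -4, 0 dB}, each trial being
2 s of noise with a static image, a variable-length sentence, and 2 s of
post-speech noise.  Three measurement streams are produced:

* pupil traces (default 1200 Hz) with an event-related dilation whose
  amplitude follows a concave quadratic effort curve in SNR, plus blink
  artifacts (extreme-amplitude spikes and missing runs);
* EEG epochs (default 64 channels, 1024 Hz, 0-7 s) of 1/f background noise
  with a theta-band burst during active listening, spatially weighted toward
  the frontal midline and scaled so the dB-baselined frontal theta estimate
  equals the planted effort value;
* keyword-recognition scores (0-3) from a logistic psychometric function.

The ground truth (true vertices and peak shift) is recorded with every
dataset so downstream recovery can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import expit

from .curves import EffortCurveParams, DEFAULT_PUPIL_PARAMS, DEFAULT_THETA_PARAMS, effort_curve
from .design import (
    StudyDesign,
    SubjectEffects,
    SubjectVariability,
    draw_subject_effects,
)
from .pupil import PupilTrace
from .spectral import EEGEpoch, SpectralConfig, log_power_bias_db

__all__ = [
    "PupilNoiseConfig",
    "EEGNoiseConfig",
    "PsychometricConfig",
    "StudyParams",
    "StudyDataset",
    "simulate_pupil_trial",
    "simulate_eeg_trial",
    "simulate_behavior",
    "simulate_study",
    "behavior_condition_table",
]


@dataclass(frozen=True)
class PupilNoiseConfig:
    """Noise and artifact model for pupil trials.

    ``amplitude_sd`` is the trial-to-trial jitter of the dilation amplitude
    (the dominant source of condition-level PPD variance); ``drift_sd`` is a
    slow (<0.5 Hz) within-trial wander; ``measurement_sd`` is white sensor
    noise.  Blinks arrive as a Poisson process and are either missing runs
    (samples invalid) or large-amplitude excursions, mirroring what an
    amplitude-threshold blink detector has to handle.
    """

    amplitude_sd: float = 0.08  # mm
    drift_sd: float = 0.02  # mm
    measurement_sd: float = 0.01  # mm
    blink_rate_hz: float = 0.15
    blink_dur_range_s: tuple[float, float] = (0.06, 0.18)
    blink_missing_prob: float = 0.5
    blink_spike_mm: float = 2.0


@dataclass(frozen=True)
class EEGNoiseConfig:
    """Noise model for EEG trials: 1/f background plus theta burst."""

    noise_rms_uv: float = 10.0
    pink_exponent: float = 1.0
    pink_floor_hz: float = 1.0
    theta_trial_sd_db: float = 0.2
    burst_band_hz: tuple[float, float] = (1.0, 12.0)
    burst_ramp_s: float = 0.15
    burst_window_s: tuple[float, float] = (2.0, 6.0)
    frontal_weight: float = 1.0
    neighbor_weight: float = 0.6
    distant_weight: float = 0.2
    alpha_contamination: float = 0.0  # optional 10 Hz background, off by default


@dataclass(frozen=True)
class PsychometricConfig:
    """Logistic keyword-recognition model: p = expit(slope * (snr - srt))."""

    srt_ao_db: float = -4.0
    srt_av_db: float = -8.0
    slope_per_db: float = 0.6
    p_vo: float = 0.1
    n_keywords: int = 3


@dataclass(frozen=True)
class StudyParams:
    """Everything that defines the generative model of a study."""

    pupil_curve: EffortCurveParams = DEFAULT_PUPIL_PARAMS
    theta_curve: EffortCurveParams = DEFAULT_THETA_PARAMS
    vo_pupil_level: float = 0.1  # mm, fixed effort level of the VO condition
    vo_theta_level: float = 0.2  # dB
    pupil_noise: PupilNoiseConfig = PupilNoiseConfig()
    eeg_noise: EEGNoiseConfig = EEGNoiseConfig()
    psychometric: PsychometricConfig = PsychometricConfig()
    subject_variability: SubjectVariability = SubjectVariability()

    def ground_truth(self) -> dict:
        """Closed-form true vertices and peak shifts, for recovery checks."""
        out = {}
        for name, curve in (("pupil", self.pupil_curve), ("theta", self.theta_curve)):
            out[name] = {
                "vertex_ao_centered": curve.vertex_centered("AO"),
                "vertex_av_centered": curve.vertex_centered("AV"),
                "vertex_ao_db": curve.vertex_db("AO"),
                "vertex_av_db": curve.vertex_db("AV"),
                "shift_db": curve.true_shift_db,
            }
        return out


def _trial_effort(
    modality: str,
    snr_db: float,
    subj: SubjectEffects,
    curve: EffortCurveParams,
    vo_level: float,
) -> float:
    """Planted effort level for one trial (before trial noise and subject
    intercept): the quadratic curve evaluated at the subject's effective SNR,
    or the fixed VO level."""
    if modality == "VO":
        return vo_level
    return float(effort_curve(snr_db - subj.srt_shift_db, modality, curve))


@lru_cache(maxsize=8)
def _drift_sos(fs: float) -> np.ndarray:
    return signal.butter(2, 0.5, btype="low", fs=fs, output="sos")


def _pupil_bump(t_s: np.ndarray, onset_s: float, peak_delay_s: float = 2.5, shape: float = 2.0):
    """Gamma-like dilation kernel, 0 before onset, unit peak ``peak_delay_s``
    after onset, slow decay afterwards."""
    tau = np.maximum(t_s - onset_s, 0.0) / peak_delay_s
    return np.where(tau > 0, tau**shape * np.exp(shape * (1.0 - tau)), 0.0)


def simulate_pupil_trial(
    modality: str,
    snr_db: float,
    subj: SubjectEffects,
    params: StudyParams,
    design: StudyDesign,
    rng: np.random.Generator,
    meta: dict | None = None,
) -> PupilTrace:
    """One trial's pupil trace: tonic level + event-related bump + artifacts.

    The bump amplitude is ``effort_curve(.) + subject intercept + trial
    noise``; the bump peaks ~2.5 s after speech onset, inside the 2-7 s
    analysis window.  With all noise and blink rates at zero the maximum of
    the baseline-corrected trace equals the planted amplitude (up to the
    sampling grid).
    """
    noise = params.pupil_noise
    speech_dur = rng.uniform(*design.speech_dur_range_s)
    duration = design.speech_onset_s + speech_dur + design.post_noise_s
    n = int(round(duration * design.fs_pupil))
    t = np.arange(n) / design.fs_pupil

    amplitude = (
        _trial_effort(modality, snr_db, subj, params.pupil_curve, params.vo_pupil_level)
        + subj.random_intercept_pupil
        + (rng.normal(0.0, noise.amplitude_sd) if noise.amplitude_sd > 0 else 0.0)
    )
    samples = subj.tonic_pupil_mm + amplitude * _pupil_bump(t, design.speech_onset_s)

    if noise.drift_sd > 0:
        drift = signal.sosfilt(_drift_sos(design.fs_pupil), rng.standard_normal(n))
        sd = drift.std()
        if sd > 0:
            samples = samples + noise.drift_sd * drift / sd
    if noise.measurement_sd > 0:
        samples = samples + rng.normal(0.0, noise.measurement_sd, n)

    valid = np.ones(n, bool)
    n_blinks = rng.poisson(noise.blink_rate_hz * duration) if noise.blink_rate_hz > 0 else 0
    for _ in range(n_blinks):
        start = int(rng.uniform(0, n))
        dur = int(rng.uniform(*noise.blink_dur_range_s) * design.fs_pupil)
        stop = min(start + max(dur, 1), n)
        if rng.uniform() < noise.blink_missing_prob:
            valid[start:stop] = False
            samples[start:stop] = 0.0  # hardware reports dropouts as zeros
        else:
            sign = -1.0 if rng.uniform() < 0.8 else 1.0  # blinks mostly shrink
            samples[start:stop] += sign * noise.blink_spike_mm

    m = dict(meta or {})
    m.setdefault("subject", subj.subject_id)
    m["modality"] = modality
    m["snr_db"] = snr_db
    return PupilTrace(
        time_s=t,
        samples=samples,
        fs=design.fs_pupil,
        valid_mask=valid,
        meta=m,
        provenance=["simulated"],
    )


def _pink_noise(
    n: int,
    fs: float,
    rng: np.random.Generator,
    cfg: EEGNoiseConfig,
    band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Gaussian 1/f^exponent noise (power spectrum), flat below the floor
    frequency.  The full-band variant is normalised to the configured RMS;
    with ``band`` the spectrum is zeroed outside the band but keeps the
    *same* spectral scale, so in-band its power density equals the
    background's exactly (the property the theta planting relies on)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = 1.0 / np.maximum(freqs, cfg.pink_floor_hz) ** (cfg.pink_exponent / 2.0)
    shaping[0] = 0.0
    full_rms = 2.0 * np.sqrt(np.sum(shaping**2)) / n
    scale = cfg.noise_rms_uv / full_rms if full_rms > 0 else 1.0
    if band is not None:
        shaping = np.where((freqs >= band[0]) & (freqs <= band[1]), shaping, 0.0)
    spec = shaping * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    return scale * np.fft.irfft(spec, n)


def _channel_weights(channels: tuple[str, ...], cfg: EEGNoiseConfig) -> np.ndarray:
    frontal = {"AF3", "AF4", "AFz"}
    neighbors = {"Fp1", "Fpz", "Fp2", "F1", "Fz", "F2"}
    w = np.full(len(channels), cfg.distant_weight)
    for i, ch in enumerate(channels):
        if ch in frontal:
            w[i] = cfg.frontal_weight
        elif ch in neighbors:
            w[i] = cfg.neighbor_weight
    return w


def planted_theta_to_burst_gain(theta_db: float, bias_db: float) -> float:
    """Burst gain beta with in-band power ratio 1 + beta^2 chosen so the
    log-then-average pipeline recovers ``theta_db`` in expectation (the
    Gaussian log-power offset ``bias_db`` is compensated)."""
    ratio = 10.0 ** ((theta_db - bias_db) / 10.0)
    return float(np.sqrt(max(ratio - 1.0, 0.0)))


def simulate_eeg_trial(
    modality: str,
    snr_db: float,
    subj: SubjectEffects,
    params: StudyParams,
    design: StudyDesign,
    rng: np.random.Generator,
    spectral_config: SpectralConfig = SpectralConfig(),
    meta: dict | None = None,
) -> EEGEpoch:
    """One trial's EEG epoch: 1/f noise + theta-band burst during listening.

    The burst is an independent 1/f realisation band-passed to the burst band
    and added during the 2-6 s window, so the in-band power ratio relative to
    baseline is exactly ``1 + beta^2`` at every in-band frequency.  ``beta``
    per channel is set from the planted effort value (frontal midline
    channels carry the full value; other sites a scaled-down copy) with the
    log-power offset of the measurement recipe compensated, so the pipeline's
    frontal theta estimate equals ``effort_curve(.) + subject intercept +
    trial noise`` in expectation.
    """
    channels = design.eeg_channels
    for ch in ("AF3", "AF4", "AFz"):
        if ch not in channels:
            raise ValueError(f"channel layout must include {ch}")
    cfg = params.eeg_noise
    fs = design.fs_eeg
    n = int(round(design.epoch_s * fs))
    t = np.arange(n) / fs

    theta_target = (
        _trial_effort(modality, snr_db, subj, params.theta_curve, params.vo_theta_level)
        + subj.random_intercept_theta
        + (rng.normal(0.0, cfg.theta_trial_sd_db) if cfg.theta_trial_sd_db > 0 else 0.0)
    )
    bias = log_power_bias_db(
        spectral_config.wavelets,
        spectral_config.theta_band_hz,
        spectral_config.baseline_window_s,
    )
    weights = _channel_weights(channels, cfg)

    lo, hi = cfg.burst_window_s
    ramp = cfg.burst_ramp_s
    env = np.zeros(n)
    inside = (t >= lo) & (t <= hi)
    env[inside] = 1.0
    if ramp > 0:
        up = inside & (t < lo + ramp)
        down = inside & (t > hi - ramp)
        env[up] = np.sin(0.5 * np.pi * (t[up] - lo) / ramp) ** 2
        env[down] = np.sin(0.5 * np.pi * (hi - t[down]) / ramp) ** 2

    data = np.empty((len(channels), n))
    for c in range(len(channels)):
        background = _pink_noise(n, fs, rng, cfg)
        if cfg.alpha_contamination > 0:
            background = background + cfg.alpha_contamination * np.sin(
                2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi)
            )
        beta = planted_theta_to_burst_gain(weights[c] * theta_target, bias)
        burst = _pink_noise(n, fs, rng, cfg, band=cfg.burst_band_hz)
        data[c] = background + beta * env * burst

    m = dict(meta or {})
    m.setdefault("subject", subj.subject_id)
    m["modality"] = modality
    m["snr_db"] = snr_db
    m["planted_theta_db"] = theta_target
    return EEGEpoch(data=data, fs=fs, channel_names=tuple(channels), t0=0.0, meta=m)


def simulate_behavior(
    modality: str,
    snr_db: float,
    subj: SubjectEffects,
    psychometric: PsychometricConfig,
    rng: np.random.Generator,
) -> int:
    """Keywords correct (0..n_keywords) from a Binomial-logistic model."""
    cfg = psychometric
    if modality == "VO":
        p = cfg.p_vo
    else:
        srt = (cfg.srt_ao_db if modality == "AO" else cfg.srt_av_db) + subj.srt_shift_db
        p = float(expit(cfg.slope_per_db * (snr_db - srt)))
    return int(rng.binomial(cfg.n_keywords, p))


@dataclass
class StudyDataset:
    """One simulated study: trial table, raw streams, and ground truth."""

    design: StudyDesign
    params: StudyParams
    seed: int
    subjects: list[SubjectEffects]
    trial_table: pd.DataFrame
    pupil_traces: list[PupilTrace] | None
    eeg_epochs: list[EEGEpoch] | None
    ground_truth: dict


def simulate_study(
    design: StudyDesign = StudyDesign(),
    params: StudyParams = StudyParams(),
    seed: int = 0,
    streams: tuple[str, ...] = ("behavior", "pupil", "eeg"),
    spectral_config: SpectralConfig = SpectralConfig(),
) -> StudyDataset:
    """Simulate a complete study, reproducibly for a fixed seed.

    ``streams`` selects which measurements to generate; EEG for a full-size
    design is large (subjects x conditions x trials x 64 channels), so
    callers running many replicates typically request ``("behavior",
    "pupil")``.  Per-subject random-number streams are spawned from the seed,
    so the same seed always yields byte-identical tables and traces.
    """
    root = np.random.SeedSequence(seed)
    effects_ss, trials_ss = root.spawn(2)
    subjects = draw_subject_effects(
        design.n_subjects, np.random.default_rng(effects_ss), params.subject_variability
    )
    subj_streams = trials_ss.spawn(design.n_subjects)

    rows = []
    pupil_traces: list[PupilTrace] | None = [] if "pupil" in streams else None
    eeg_epochs: list[EEGEpoch] | None = [] if "eeg" in streams else None
    for subj, ss in zip(subjects, subj_streams):
        rng = np.random.default_rng(ss)
        for modality, snr_db in design.conditions():
            for trial in range(design.n_trials_per_condition):
                meta = {"subject": subj.subject_id, "trial": trial}
                score = simulate_behavior(modality, snr_db, subj, params.psychometric, rng)
                rows.append(
                    {
                        "subject": subj.subject_id,
                        "modality": modality,
                        "snr_db": snr_db,
                        "trial": trial,
                        "keywords_correct": score,
                    }
                )
                if pupil_traces is not None:
                    pupil_traces.append(
                        simulate_pupil_trial(
                            modality, snr_db, subj, params, design, rng, meta=dict(meta)
                        )
                    )
                if eeg_epochs is not None:
                    eeg_epochs.append(
                        simulate_eeg_trial(
                            modality,
                            snr_db,
                            subj,
                            params,
                            design,
                            rng,
                            spectral_config=spectral_config,
                            meta=dict(meta),
                        )
                    )

    table = pd.DataFrame(rows)
    truth = params.ground_truth()
    truth["seed"] = seed
    return StudyDataset(
        design=design,
        params=params,
        seed=seed,
        subjects=subjects,
        trial_table=table,
        pupil_traces=pupil_traces,
        eeg_epochs=eeg_epochs,
        ground_truth=truth,
    )


def behavior_condition_table(dataset: StudyDataset) -> pd.DataFrame:
    """Condition-level proportion-correct table (VO excluded), one row per
    subject x modality x SNR — the input to the behavioral mixed model."""
    df = dataset.trial_table
    df = df[df["modality"] != "VO"]
    n_kw = dataset.params.psychometric.n_keywords
    out = (
        df.groupby(["subject", "modality", "snr_db"], sort=True)["keywords_correct"]
        .mean()
        .div(n_kw)
        .rename("score_proportion")
        .reset_index()
    )
    return out
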