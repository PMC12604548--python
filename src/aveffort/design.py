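"""Study design, subject-level random effects, and the electrode montage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StudyDesign", "SubjectEffects", "SubjectVariability", "STANDARD_64_MONTAGE"]

#: Extended 10-20 (10-10) labels for a 64-channel cap.  The anterior-frontal
#: midline triplet AF3/AFz/AF4 used for frontal midline theta is included.
STANDARD_64_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout and acquisition parameters of one study.

    Two speech modalities (auditory-only AO, audiovisual AV) crossed with four
    SNRs, plus a visual-only (VO) condition without an SNR manipulation.  Each
    trial is 2 s of noise/static image, a variable-length sentence, and 2 s of
    post-speech noise; EEG epochs are trimmed to a fixed 7 s from noise onset
    while pupil traces keep their full variable length.
    """

    n_subjects: int = 22
    modalities: tuple[str, ...] = ("AO", "AV", "VO")
    snrs_db: tuple[float, ...] = (-12.0, -8.0, -4.0, 0.0)
    n_trials_per_condition: int = 20
    fs_pupil: float = 1200.0
    fs_eeg: float = 1024.0
    epoch_s: float = 7.0
    baseline_s: float = 2.0
    speech_onset_s: float = 2.0
    speech_dur_range_s: tuple[float, float] = (3.87, 5.4)
    post_noise_s: float = 2.0
    eeg_channels: tuple[str, ...] = STANDARD_64_MONTAGE

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ValueError("n_subjects and n_trials_per_condition must be >= 1")
        if self.fs_pupil <= 0 or self.fs_eeg <= 0:
            raise ValueError("sampling rates must be positive")
        snrs = np.asarray(self.snrs_db, float)
        if len(snrs) < 2 or not np.all(np.diff(snrs) > 0):
            raise ValueError("snrs_db must be strictly increasing")
        if self.epoch_s < self.baseline_s + 1.0:
            raise ValueError("epoch must cover the baseline plus an active window")
        lo, hi = self.speech_dur_range_s
        if not (0 < lo <= hi):
            raise ValueError("invalid speech duration range")

    def conditions(self) -> list[tuple[str, float]]:
        """All (modality, snr_db) cells; the VO cell carries snr_db = nan."""
        cells: list[tuple[str, float]] = []
        for mod in self.modalities:
            if mod == "VO":
                cells.append(("VO", float("nan")))
            else:
                cells.extend((mod, float(s)) for s in self.snrs_db)
        return cells


@dataclass(frozen=True)
class SubjectVariability:
    """Standard deviations of the zero-mean subject-level random effects."""

    pupil_intercept_sd: float = 0.03  # mm, shifts a subject's PPD level
    theta_intercept_sd: float = 0.3  # dB, shifts a subject's theta level
    srt_shift_sd: float = 1.5  # dB, shifts the psychometric + effort curves
    tonic_pupil_mm: float = 3.5  # mean resting pupil size
    tonic_pupil_sd: float = 0.4


@dataclass(frozen=True)
class SubjectEffects:
    """One subject's draw from the random-effect distributions."""

    subject_id: str
    random_intercept_pupil: float = 0.0
    random_intercept_theta: float = 0.0
    srt_shift_db: float = 0.0
    tonic_pupil_mm: float = 3.5


def draw_subject_effects(
    n_subjects: int,
    rng: np.random.Generator,
    variability: SubjectVariability = SubjectVariability(),
) -> list[SubjectEffects]:
    """Draw per-subject random effects from zero-mean normals."""
    out = []
    for i in range(n_subjects):
        out.append(
            SubjectEffects(
                subject_id=f"S{i + 1:02d}",
                random_intercept_pupil=rng.normal(0.0, variability.pupil_intercept_sd),
                random_intercept_theta=rng.normal(0.0, variability.theta_intercept_sd),
                srt_shift_db=rng.normal(0.0, variability.srt_shift_sd),
                tonic_pupil_mm=rng.normal(
                    variability.tonic_pupil_mm, variability.tonic_pupil_sd
                ),
            )
        )
    return out
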