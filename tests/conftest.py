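import numpy as np
import pandas as pd
import pytest

from aveffort.design import StudyDesign, SubjectVariability
from aveffort.simulate import (
    EEGNoiseConfig,
    PupilNoiseConfig,
    StudyParams,
    simulate_study,
)

#: Small montage with the frontal midline triplet, used for fast EEG tests.
SMALL_MONTAGE = ("Fp1", "AF3", "AFz", "AF4", "Fz", "Cz", "Pz", "Oz")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_params():
    """Generator parameters with every noise source and random effect off."""
    return StudyParams(
        pupil_noise=PupilNoiseConfig(
            amplitude_sd=0.0, drift_sd=0.0, measurement_sd=0.0, blink_rate_hz=0.0
        ),
        eeg_noise=EEGNoiseConfig(theta_trial_sd_db=0.0),
        subject_variability=SubjectVariability(
            pupil_intercept_sd=0.0, theta_intercept_sd=0.0, srt_shift_sd=0.0, tonic_pupil_sd=0.0
        ),
    )


@pytest.fixture
def small_design():
    return StudyDesign(
        n_subjects=3,
        n_trials_per_condition=2,
        eeg_channels=SMALL_MONTAGE,
        fs_eeg=256.0,
    )


@pytest.fixture
def tiny_pupil_study(small_design, noiseless_params):
    return simulate_study(
        small_design, noiseless_params, seed=7, streams=("behavior", "pupil")
    )


def simulate_condition_table(
    beta: dict,
    n_subjects: int,
    rng: np.random.Generator,
    sigma_subject: float = 0.0,
    sigma_resid: float = 0.02,
    outcome: str = "ppd",
    center: float = -6.0,
) -> pd.DataFrame:
    """Condition-level data drawn directly from the mixed model itself.

    An independent oracle generator for model-fitting tests: no traces, no
    preprocessing — just the linear predictor plus Gaussian noise.
    """
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0.0, sigma_subject) if sigma_subject > 0 else 0.0
        for mod in ("AO", "AV"):
            av = 1.0 if mod == "AV" else 0.0
            for snr in (-12.0, -8.0, -4.0, 0.0):
                x = snr - center
                mu = (
                    beta.get("intercept", 0.0)
                    + beta.get("mod", 0.0) * av
                    + beta.get("snr", 0.0) * x
                    + beta.get("mod:snr", 0.0) * av * x
                    + beta.get("snr2", 0.0) * x * x
                    + beta.get("mod:snr2", 0.0) * av * x * x
                )
                rows.append(
                    {
                        "subject": f"S{s:02d}",
                        "modality": mod,
                        "snr_db": snr,
                        outcome: mu + u + rng.normal(0.0, sigma_resid),
                    }
                )
    return pd.DataFrame(rows)
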