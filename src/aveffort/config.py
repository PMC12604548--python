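"""Pipeline configuration: one object holding every tunable, YAML round-trip.

A ``PipelineConfig`` bundles the study design, the generative parameters,
and the preprocessing/model/inference settings, together with the master
seed.  Its on-disk YAML form round-trips losslessly, and a SHA-256 hash of
the canonical serialisation identifies a configuration in run manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, fields, is_dataclass
from pathlib import Path

import yaml

from .curves import EffortCurveParams
from .design import StudyDesign, SubjectVariability
from .pupil import PupilConfig
from .simulate import EEGNoiseConfig, PsychometricConfig, PupilNoiseConfig, StudyParams
from .spectral import SpectralConfig, WaveletSpec

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class PeaksConfig:
    n_draws: int = 1000
    concavity_filter: bool = False


@dataclass(frozen=True)
class ModelsConfig:
    center_snr: float = -6.0


@dataclass(frozen=True)
class PipelineConfig:
    design: StudyDesign = StudyDesign()
    params: StudyParams = StudyParams()
    pupil: PupilConfig = PupilConfig()
    spectral: SpectralConfig = SpectralConfig()
    models: ModelsConfig = ModelsConfig()
    peaks: PeaksConfig = PeaksConfig()
    streams: tuple[str, ...] = ("behavior", "pupil", "eeg")
    seed: int = 0


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _build(cls, data):
    """Rebuild a dataclass from plain data, coercing lists back to tuples."""
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = _NESTED.get((cls, f.name))
        if sub is not None and v is not None:
            kwargs[f.name] = _build(sub, v)
        elif isinstance(v, list):
            kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


_NESTED = {
    (PipelineConfig, "design"): StudyDesign,
    (PipelineConfig, "params"): StudyParams,
    (PipelineConfig, "pupil"): PupilConfig,
    (PipelineConfig, "spectral"): SpectralConfig,
    (PipelineConfig, "models"): ModelsConfig,
    (PipelineConfig, "peaks"): PeaksConfig,
    (StudyParams, "pupil_curve"): EffortCurveParams,
    (StudyParams, "theta_curve"): EffortCurveParams,
    (StudyParams, "pupil_noise"): PupilNoiseConfig,
    (StudyParams, "eeg_noise"): EEGNoiseConfig,
    (StudyParams, "psychometric"): PsychometricConfig,
    (StudyParams, "subject_variability"): SubjectVariability,
    (SpectralConfig, "wavelets"): WaveletSpec,
}


def config_to_dict(config: PipelineConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> PipelineConfig:
    return _build(PipelineConfig, data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
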