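"""Interchange formats: pupil TSV, EEG float32 + JSON sidecar or EDF, tables.

Numeric payloads round-trip losslessly (float32 for bulk traces, full
precision for tables); schema problems raise errors naming the missing
column or channel.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .pupil import PupilTrace
from .spectral import EEGEpoch

__all__ = [
    "write_pupil_tsv",
    "read_pupil_tsv",
    "write_trial_table",
    "read_trial_table",
    "write_eeg_epochs",
    "read_eeg_epochs",
    "read_edf_recording",
    "write_json",
    "read_json",
]

PUPIL_COLUMNS = [
    "subject",
    "trial",
    "modality",
    "snr_db",
    "time_s",
    "pupil_left",
    "pupil_right",
    "valid_flag",
]


def write_pupil_tsv(traces: list[PupilTrace], path: str | Path) -> None:
    """Long-format TSV of pupil trials.

    The package-internal trace is monocular (two eyes already combined); on
    disk both eye columns are written with the same values so the layout
    matches binocular eye-tracker exports.
    """
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "subject": tr.meta.get("subject", "?"),
                    "trial": tr.meta.get("trial", 0),
                    "modality": tr.meta.get("modality", "?"),
                    "snr_db": tr.meta.get("snr_db", np.nan),
                    "time_s": tr.time_s,
                    "pupil_left": tr.samples.astype(np.float32),
                    "pupil_right": tr.samples.astype(np.float32),
                    "valid_flag": tr.valid_mask.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_pupil_tsv(
    path: str | Path, fs: float, column_map: dict | None = None
) -> list[PupilTrace]:
    """Read a long-format pupil TSV back into per-trial traces.

    ``column_map`` renames vendor-specific export columns onto the canonical
    schema.  Both eyes are combined by averaging where both are valid and
    taking the valid one otherwise.  Extra columns are ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in PUPIL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pupil table lacks columns: {missing}")
    extra = [c for c in df.columns if c not in PUPIL_COLUMNS]
    if extra:
        warnings.warn(f"ignoring extra pupil-table columns: {extra}")
    traces = []
    for (subj, trial, mod, snr), grp in df.groupby(
        ["subject", "trial", "modality", "snr_db"], dropna=False, sort=True
    ):
        grp = grp.sort_values("time_s")
        left = grp["pupil_left"].to_numpy(float)
        right = grp["pupil_right"].to_numpy(float)
        valid = grp["valid_flag"].to_numpy() > 0
        ok_l = np.isfinite(left)
        ok_r = np.isfinite(right)
        both = ok_l & ok_r
        samples = np.where(both, 0.5 * (left + right), np.where(ok_l, left, right))
        samples = np.where(ok_l | ok_r, samples, 0.0)
        traces.append(
            PupilTrace(
                time_s=grp["time_s"].to_numpy() - grp["time_s"].iloc[0],
                samples=samples,
                fs=fs,
                valid_mask=valid & (ok_l | ok_r),
                meta={
                    "subject": subj,
                    "trial": int(trial),
                    "modality": mod,
                    "snr_db": float(snr) if pd.notna(snr) else np.nan,
                },
            )
        )
    return traces


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} lacks columns: {missing}")
    return df


def write_eeg_epochs(epochs: list[EEGEpoch], directory: str | Path) -> None:
    """Raw float32 array file plus JSON sidecar (channels, fs, epoch metas)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not epochs:
        raise ValueError("no epochs to write")
    shape = epochs[0].data.shape
    if any(e.data.shape != shape for e in epochs):
        raise ValueError("all epochs must share one shape")
    data = np.stack([e.data for e in epochs]).astype(np.float32)
    data.tofile(directory / "epochs.f32")
    sidecar = {
        "n_epochs": len(epochs),
        "n_channels": shape[0],
        "n_samples": shape[1],
        "fs": epochs[0].fs,
        "t0": epochs[0].t0,
        "channel_names": list(epochs[0].channel_names),
        "dtype": "float32",
        "metas": [_jsonable(e.meta) for e in epochs],
    }
    (directory / "epochs.json").write_text(json.dumps(sidecar, indent=1))


def read_eeg_epochs(directory: str | Path) -> list[EEGEpoch]:
    directory = Path(directory)
    sidecar = json.loads((directory / "epochs.json").read_text())
    data = np.fromfile(directory / "epochs.f32", dtype=np.float32).reshape(
        sidecar["n_epochs"], sidecar["n_channels"], sidecar["n_samples"]
    )
    names = tuple(sidecar["channel_names"])
    return [
        EEGEpoch(
            data=data[i].astype(float),
            fs=sidecar["fs"],
            channel_names=names,
            t0=sidecar["t0"],
            meta=sidecar["metas"][i],
        )
        for i in range(sidecar["n_epochs"])
    ]


def read_edf_recording(
    path: str | Path, required_channels: tuple[str, ...] = ()
) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read an EDF recording; returns (data channels x samples, fs, names)."""
    from mne.io import read_raw_edf

    raw = read_raw_edf(str(path), preload=True, verbose="error")
    names = tuple(raw.ch_names)
    for ch in required_channels:
        if ch not in names:
            raise ValueError(f"EDF recording {path} lacks required channel {ch}")
    return raw.get_data(), float(raw.info["sfreq"]), names


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
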