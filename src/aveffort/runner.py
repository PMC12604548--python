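"""Full-study orchestration: simulate -> pupil -> eeg -> fits -> peaks.

``run_all`` executes the whole pipeline for one configuration and seed,
writing every intermediate table and a run manifest sufficient to reproduce
the run exactly.  A master seed spawns per-stage seeds so stages can be
re-run in isolation with identical results.
"""

from __future__ import annotations

import datetime
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash, save_config
from .io import write_json, write_pupil_tsv, write_trial_table, write_eeg_epochs
from .models import ModelSpec, fit_lmm, wald_tests
from .peaks import draw_posterior, peak_posterior, peak_shift_inference, vertex_from_coefficients
from .pupil import process_pupil_trials
from .simulate import behavior_condition_table, simulate_study
from .spectral import theta_from_epochs

__all__ = ["run_all", "RunManifest"]


@dataclass
class RunManifest:
    package_version: str
    config_sha256: str
    master_seed: int
    stage_seeds: dict
    row_counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    started_utc: str = ""
    finished_utc: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _fit_and_infer(table, outcome, n_draws, rng, center_snr, concavity_filter):
    fit = fit_lmm(table, ModelSpec(outcome=outcome, center_snr=center_snr))
    tests = wald_tests(fit)
    payload = fit.to_dict()
    payload["wald"] = tests.reset_index().to_dict(orient="records")
    result = None
    if "snr2" in fit.names:
        draws = draw_posterior(fit, n_draws=n_draws, rng=rng)
        post = peak_posterior(draws, center_snr=center_snr)
        result = peak_shift_inference(post, concavity_filter=concavity_filter)
        payload["plugin_peaks"] = vertex_from_coefficients(fit.beta)
    return fit, payload, result


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    write_raw: bool = False,
) -> dict:
    """Run the complete pipeline; returns the result dictionary.

    Writes condition-level tables, model summaries, shift results, and the
    manifest under ``out_dir``.  With ``write_raw`` the simulated raw pupil
    TSV and EEG epochs are written too (large for full-size designs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_ss = np.random.SeedSequence(config.seed).spawn(3)
    stage_seeds = {
        "simulate": config.seed,
        "ppd_draws": int(stage_ss[1].generate_state(1)[0] % (2**31)),
        "theta_draws": int(stage_ss[2].generate_state(1)[0] % (2**31)),
    }
    manifest = RunManifest(
        package_version=__version__,
        config_sha256=config_hash(config),
        master_seed=config.seed,
        stage_seeds=stage_seeds,
        started_utc=_now(),
    )
    save_config(config, out / "config.yaml")

    stage = "simulate"
    try:
        study = simulate_study(
            design=config.design,
            params=config.params,
            seed=config.seed,
            streams=config.streams,
            spectral_config=config.spectral,
        )
        write_trial_table(study.trial_table, out / "trial_table.csv")
        write_json(study.ground_truth, out / "ground_truth.json")
        manifest.row_counts["trials"] = len(study.trial_table)
        results: dict = {"ground_truth": study.ground_truth}

        behav = behavior_condition_table(study)
        write_trial_table(behav, out / "behavior_conditions.csv")
        manifest.row_counts["behavior_conditions"] = len(behav)
        stage = "fit:behavior"
        _, payload, _ = _fit_and_infer(
            behav, "score_proportion", config.peaks.n_draws, None,
            config.models.center_snr, config.peaks.concavity_filter,
        )
        write_json(payload, out / "fit_behavior.json")
        results["behavior_fit"] = payload

        if study.pupil_traces is not None:
            stage = "pupil"
            if write_raw:
                write_pupil_tsv(study.pupil_traces, out / "pupil_traces.tsv")
            ppd, report = process_pupil_trials(study.pupil_traces, config.pupil)
            write_trial_table(ppd, out / "ppd_conditions.csv")
            write_json(report.to_dict(), out / "pupil_exclusions.json")
            manifest.row_counts["ppd_conditions"] = len(ppd)
            manifest.exclusions["pupil"] = {
                "trials": len(report.trials_excluded),
                "subjects": report.subjects_excluded,
            }
            stage = "fit:ppd"
            model_tab = ppd[ppd["modality"] != "VO"].reset_index(drop=True)
            manifest.row_counts["ppd_model_rows"] = len(model_tab)
            rng = np.random.default_rng(stage_seeds["ppd_draws"])
            _, payload, shift = _fit_and_infer(
                model_tab, "ppd", config.peaks.n_draws, rng,
                config.models.center_snr, config.peaks.concavity_filter,
            )
            write_json(payload, out / "fit_ppd.json")
            write_json(shift.to_dict(), out / "shift_ppd.json")
            results["ppd_fit"] = payload
            results["ppd_shift"] = shift

        if study.eeg_epochs is not None:
            stage = "eeg"
            if write_raw:
                write_eeg_epochs(study.eeg_epochs, out / "eeg_epochs")
            theta = theta_from_epochs(study.eeg_epochs, config.spectral)
            df = pd.DataFrame(
                {
                    "subject": [e.meta["subject"] for e in study.eeg_epochs],
                    "modality": [e.meta["modality"] for e in study.eeg_epochs],
                    "snr_db": [e.meta["snr_db"] for e in study.eeg_epochs],
                    "theta_db": theta,
                }
            )
            cond = (
                df.groupby(["subject", "modality", "snr_db"], dropna=False, sort=True)[
                    "theta_db"
                ]
                .mean()
                .reset_index()
            )
            write_trial_table(cond, out / "theta_conditions.csv")
            stage = "fit:theta"
            model_tab = cond[cond["modality"] != "VO"].dropna(subset=["snr_db"])
            model_tab = model_tab.reset_index(drop=True)
            manifest.row_counts["theta_model_rows"] = len(model_tab)
            rng = np.random.default_rng(stage_seeds["theta_draws"])
            _, payload, shift = _fit_and_infer(
                model_tab, "theta_db", config.peaks.n_draws, rng,
                config.models.center_snr, config.peaks.concavity_filter,
            )
            write_json(payload, out / "fit_theta.json")
            write_json(shift.to_dict(), out / "shift_theta.json")
            results["theta_fit"] = payload
            results["theta_shift"] = shift
    except Exception as err:
        manifest.finished_utc = _now()
        manifest.row_counts["failed_stage"] = stage
        write_json(manifest.to_dict(), out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    manifest.finished_utc = _now()
    write_json(manifest.to_dict(), out / "manifest.json")
    results["manifest"] = manifest
    return results
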