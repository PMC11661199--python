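"""End-to-end orchestration: simulate -> screen -> summarise -> reliability
-> EZ -> (optional) hierarchical fits, transfer and embedded correlations.

A :class:`PipelineConfig` (round-trippable to YAML) drives every stage;
each stage writes its table into the run directory and the manifest records
the config, seeds and stage list, so a rerun with the same config
reproduces all non-MCMC artifacts bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import CohortData
from .ddm_model import ez_per_session, fit_hierarchical_ddm
from .embedded_reliability import EmbeddedSpec, fit_embedded
from .gonogo_model import fit_hierarchical_gng
from .hierarchical import McmcConfig
from .io import read_trials, write_trials
from .predictive_transfer import transfer_table, transfer_tests
from .reliability import reliability_table
from .summary_statistics import (
    apply_exclusions, exclusion_frame, session_summaries,
)
from .synthetic_cohort import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

_SUMMARY_MEASURES = {
    "gonogo": ["acc_go_to_win", "acc_nogo_to_win",
               "acc_go_to_avoid", "acc_nogo_to_avoid"],
    "ambiguous_midpoint": ["p_high_mid"],
}


@dataclass
class PipelineConfig:
    """Everything one run needs; all seeds explicit."""

    out_dir: str = "runs/demo"
    tasks: tuple[str, ...] = ("gonogo", "ambiguous_midpoint")
    n_subjects: int = 58
    seed: int = 0
    cross_session_r: float = 0.7
    apply_exclusions: bool = True
    run_ez: bool = True
    run_fits: bool = False
    run_transfer: bool = False
    run_embedded: bool = False
    gng_model_id: str = "rw_go_pav_split"
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    trials_path: str | None = None  # fit existing data instead of simulating

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tasks"] = list(self.tasks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = McmcConfig(**d["mcmc"])
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"config_hash": _config_hash(config),
                "version": __version__, "stages": []}
    stage = "init"
    try:
        cohorts: dict[str, CohortData] = {}
        stage = "simulate"
        for i, task in enumerate(config.tasks):
            if config.trials_path:
                data = read_trials(config.trials_path)
                data.trials = data.trials[data.trials["task"] == task]
                cohorts[task] = data
            else:
                cc = CohortConfig(task=task, n_subjects=config.n_subjects,
                                  cross_session_r=config.cross_session_r,
                                  seed=config.seed + i)
                cohorts[task] = simulate_cohort(cc)
            write_trials(cohorts[task], out / f"trials_{task}.csv")
        manifest["stages"].append("simulate")

        stage = "exclusions"
        if config.apply_exclusions:
            for task in config.tasks:
                cohorts[task], reports = apply_exclusions(cohorts[task])
                exclusion_frame(reports).to_csv(
                    out / f"exclusions_{task}.csv", index=False)
            manifest["stages"].append("exclusions")

        stage = "summarise"
        rel_frames = []
        for task in config.tasks:
            summ = session_summaries(cohorts[task])
            summ.to_csv(out / f"summaries_{task}.csv", index=False)
            s1 = summ[summ["session"] == 1]
            s2 = summ[summ["session"] == 2]
            rel_frames.append(reliability_table(
                s1, s2, measures=_SUMMARY_MEASURES[task], task=task))
        reliability = pd.concat(rel_frames, ignore_index=True)
        reliability.to_csv(out / "reliability_summary_stats.csv", index=False)
        manifest["stages"].append("summarise")

        if config.run_ez and "ambiguous_midpoint" in config.tasks:
            stage = "ez"
            am = cohorts["ambiguous_midpoint"]
            ez = ez_per_session(am.sessions(task="ambiguous_midpoint"))
            ez.to_csv(out / "ez_estimates.csv", index=False)
            s1 = ez[ez["session"] == 1].drop(columns=["session", "flags"])
            s2 = ez[ez["session"] == 2].drop(columns=["session", "flags"])
            reliability_table(s1, s2, measures=["v", "a", "ter"],
                              task="ambiguous_midpoint").to_csv(
                out / "reliability_ez.csv", index=False)
            manifest["stages"].append("ez")

        fits = {}
        if config.run_fits:
            stage = "fit"
            for task in config.tasks:
                cohort = cohorts[task]
                by_no = {s: cohort.sessions(task=task, session=s)
                         for s in (1, 2)}
                for sess_no in (1, 2):
                    if task == "gonogo":
                        fit = fit_hierarchical_gng(
                            by_no[sess_no], model_id=config.gng_model_id,
                            mcmc=config.mcmc)
                    else:
                        fit = fit_hierarchical_ddm(by_no[sess_no],
                                                   mcmc=config.mcmc)
                    fit.save(out / f"fit_{task}_s{sess_no}")
                    fits[(task, sess_no)] = fit
                s1m = fits[(task, 1)].subject_means
                s2m = fits[(task, 2)].subject_means
                reliability_table(
                    s1m, s2m,
                    measures=[c for c in s1m.columns if c != "subject"],
                    task=task).to_csv(
                    out / f"reliability_params_{task}.csv", index=False)
            manifest["stages"].append("fit")

        if config.run_transfer and fits:
            stage = "transfer"
            for task in config.tasks:
                by_no = {s: cohorts[task].sessions(task=task, session=s)
                         for s in (1, 2)}
                table = transfer_table(
                    {1: fits[(task, 1)], 2: fits[(task, 2)]}, by_no, task,
                    force=True)
                table.to_csv(out / f"transfer_{task}.csv", index=False)
                transfer_tests(table).to_csv(
                    out / f"transfer_tests_{task}.csv", index=False)
            manifest["stages"].append("transfer")

        if config.run_embedded:
            stage = "embedded"
            for task in config.tasks:
                model = ("ddm4" if task == "ambiguous_midpoint"
                         else config.gng_model_id)
                spec = EmbeddedSpec(model=model, mcmc=config.mcmc)
                result = fit_embedded(cohorts[task], spec)
                result.table().to_csv(out / f"embedded_{task}.csv",
                                      index=False)
            manifest["stages"].append("embedded")
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.exception("pipeline failed at stage %s", stage)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
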