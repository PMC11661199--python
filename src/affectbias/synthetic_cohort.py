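"""Two-session synthetic cohorts with known cross-session correlations.

Subject-level parameters for the two sessions are drawn, per parameter,
from a bivariate normal on the unconstrained scale (where the hierarchical
models place their population distributions) with a configurable
correlation, then mapped to the native scale.  Simulated agents then play
the task schedules through the same choice rules the models assume, so the
generating parameters are the ground truth for recovery and reliability
studies.  Every random draw descends from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import defaults
from .datatypes import CohortData, SubjectSessionData
from .ddm_model import DDMParams, sample_wiener
from .gonogo_model import FULL_PARAMS, GNGLatentState, GNGParams, p_go, update_state
from .task_designs import (
    AMSchedule, GoNogoSchedule, am_feedback, generate_am_schedule,
    generate_gonogo_schedule, gonogo_feedback,
)
from .transforms import ParamTransform

_TASKS = ("gonogo", "ambiguous_midpoint")


@dataclass
class CohortConfig:
    """Generating distributions for one task's two-session cohort."""

    task: str = "gonogo"
    n_subjects: int = 58
    group_mean: dict[str, float] = dc_field(default_factory=dict)
    group_sd: dict[str, float] = dc_field(default_factory=dict)
    cross_session_r: dict[str, float] | float = defaults.DEFAULT_CROSS_SESSION_R
    seed: int = 0

    def __post_init__(self):
        if self.task not in _TASKS:
            raise ValueError(f"task must be one of {_TASKS}")
        base = (defaults.GNG_GROUP_DEFAULTS if self.task == "gonogo"
                else defaults.DDM_GROUP_DEFAULTS)
        mean = {p: m for p, (m, _) in base.items()}
        sd = {p: s for p, (_, s) in base.items()}
        mean.update(self.group_mean)
        sd.update(self.group_sd)
        self.group_mean, self.group_sd = mean, sd
        if isinstance(self.cross_session_r, (int, float)):
            self.cross_session_r = {p: float(self.cross_session_r) for p in mean}
        for p, r in self.cross_session_r.items():
            if abs(r) > 1:
                raise ValueError(f"|cross_session_r[{p}]| must be <= 1")
        for p, s in self.group_sd.items():
            if s < 0:
                raise ValueError(f"group_sd[{p}] must be >= 0")

    @property
    def param_names(self) -> list[str]:
        return list(self.group_mean)

    def transforms(self) -> list[ParamTransform]:
        return [ParamTransform(p, defaults.GENERATOR_TRANSFORMS[p])
                for p in self.param_names]


def sample_paired_params(config: CohortConfig,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Draw per-subject session-1/session-2 parameter pairs (native scale).

    Columns: subject, parameter, session1, session2.  The pair is bivariate
    normal on the unconstrained scale with the configured correlation, then
    transformed parameter-wise to the native scale.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    for tr in config.transforms():
        m = config.group_mean[tr.name]
        s = config.group_sd[tr.name]
        r = config.cross_session_r[tr.name]
        z = rng.standard_normal((config.n_subjects, 2))
        z2 = r * z[:, 0] + np.sqrt(max(1.0 - r * r, 0.0)) * z[:, 1]
        pair_u = np.column_stack([m + s * z[:, 0], m + s * z2])
        pair = tr.to_native(pair_u)
        for i in range(config.n_subjects):
            rows.append((i, tr.name, pair[i, 0], pair[i, 1]))
    return pd.DataFrame(rows, columns=["subject", "parameter",
                                       "session1", "session2"])


def simulate_gng_agent(params: GNGParams, schedule: GoNogoSchedule,
                       seed: int | np.random.SeedSequence) -> SubjectSessionData:
    """Simulate one go/no-go session from the generative choice rule."""
    rng = np.random.default_rng(seed)
    state = GNGLatentState()
    rows = []
    for t, trial in enumerate(schedule.trials):
        pg = p_go(state, params, trial.cue_type)
        action = "go" if rng.random() < pg else "nogo"
        outcome = gonogo_feedback(trial, action)
        rows.append((t, trial.cue_type, action, np.nan, outcome))
        state = update_state(state, params, trial.cue_type, action, outcome)
    trials = pd.DataFrame(rows, columns=["trial", "condition", "choice",
                                         "rt", "outcome"])
    return SubjectSessionData("agent", 1, "gonogo", trials)


def simulate_ddm_agent(params: DDMParams, schedule: AMSchedule,
                       seed: int | np.random.SeedSequence,
                       trained_drift: float = defaults.TRAINED_DRIFT,
                       rt_cap: float | None = None) -> SubjectSessionData:
    """Simulate one ambiguous-midpoint session.

    Midpoint trials draw (choice, RT) from the subject's Wiener process with
    the high-reward key as the upper boundary.  Trained (small/large) trials
    use the same process with drift ``+/- trained_drift`` toward the trained
    key, giving near-ceiling accuracy with realistic RTs.  ``rt_cap``
    optionally truncates RTs at a response deadline.
    """
    rng = np.random.default_rng(seed)
    all_trials = list(schedule.training_trials) + list(schedule.main_trials)
    # batch first-passage draws per distinct drift to amortise the CDF grids
    drift_of = {"mid": params.delta, "large": trained_drift,
                "small": -trained_drift}
    counts = {k: 0 for k in drift_of}
    for trial in all_trials:
        counts[trial.circle_size] += 1
    pools = {}
    for size, drift in drift_of.items():
        if counts[size] == 0:
            continue
        p = DDMParams(params.alpha, params.beta, drift, params.tau)
        pools[size] = list(zip(*sample_wiener(p, counts[size], rng)))
    rows = []
    for t, trial in enumerate(all_trials):
        rt, upper = pools[trial.circle_size].pop()
        if rt_cap is not None:
            rt = min(rt, rt_cap)
        choice = "key_high" if upper else "key_low"
        outcome = am_feedback(trial, choice)
        cond = (f"train_{trial.circle_size}" if trial.phase == "training"
                else trial.circle_size)
        rows.append((t, cond, choice, float(rt), outcome))
    trials = pd.DataFrame(rows, columns=["trial", "condition", "choice",
                                         "rt", "outcome"])
    return SubjectSessionData("agent", 1, "ambiguous_midpoint", trials)


def _gng_params_from(native_row: dict) -> GNGParams:
    return GNGParams(**{p: native_row[p] for p in FULL_PARAMS})


def _ddm_params_from(native_row: dict) -> DDMParams:
    return DDMParams(alpha=native_row["alpha"], beta=native_row["beta"],
                     delta=native_row["delta"], tau=native_row["tau"])


def simulate_cohort(config: CohortConfig,
                    schedules: dict[int, GoNogoSchedule | AMSchedule] | None = None
                    ) -> CohortData:
    """Simulate every subject in both sessions; keep the true parameters.

    For the go/no-go task each subject-session gets its own seeded trial
    order; the ambiguous-midpoint task reuses one seeded order per session
    for all subjects (as the task does).  Returns trials plus the
    true-parameter table for recovery scoring.
    """
    root = np.random.SeedSequence(config.seed)
    ss_params, ss_sched, ss_agents = root.spawn(3)
    params_tbl = sample_paired_params(
        config, np.random.default_rng(ss_params))

    if schedules is None:
        sched_seeds = [int(s.generate_state(1)[0] % (2**31))
                       for s in ss_sched.spawn(2)]
        if config.task == "ambiguous_midpoint":
            schedules = {s + 1: generate_am_schedule(sched_seeds[s])
                         for s in (0, 1)}
        else:
            schedules = {s + 1: sched_seeds[s] for s in (0, 1)}  # base seeds

    agent_seeds = ss_agents.spawn(config.n_subjects * 2)
    frames = []
    wide = params_tbl.pivot(index="subject", columns="parameter")
    for i in range(config.n_subjects):
        for sess in (1, 2):
            native = {p: wide[(f"session{sess}", p)].loc[i]
                      for p in config.param_names}
            seed = agent_seeds[2 * i + (sess - 1)]
            if config.task == "gonogo":
                base = schedules[sess]
                sched = (base if isinstance(base, GoNogoSchedule)
                         else generate_gonogo_schedule(base + i))
                data = simulate_gng_agent(_gng_params_from(native), sched, seed)
            else:
                data = simulate_ddm_agent(_ddm_params_from(native),
                                          schedules[sess], seed)
            df = data.trials.copy()
            df.insert(0, "task", config.task)
            df.insert(0, "session", sess)
            df.insert(0, "subject", i)
            frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    manifest = {
        "task": config.task,
        "n_subjects": config.n_subjects,
        "seed": config.seed,
        "group_mean": config.group_mean,
        "group_sd": config.group_sd,
        "cross_session_r": config.cross_session_r,
        "defaults_version": defaults.DEFAULTS_VERSION,
    }
    return CohortData(trials=trials, true_params=params_tbl, manifest=manifest)
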