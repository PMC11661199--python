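"""Joint two-session modelling with embedded cross-session correlations.

Instead of correlating per-session point estimates (which attenuates under
estimation noise), both sessions are fitted in one generative model whose
subject-level parameters are, per parameter, bivariate normal across
sessions on the unconstrained scale.  The cross-session correlation of each
parameter carries a uniform (LKJ shape 1 for a 2x2 block) prior and is
estimated jointly with everything else, so its posterior propagates the
estimation uncertainty of the subject-level values.  Session means and
standard deviations are free per session, making the correlation a
consistency-like quantity robust to practice effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CohortData, SubjectSessionData
from .ddm_model import _ddm_loglik_closure, _packed_mid_trials, ddm_transforms
from .gonogo_model import (
    expand_to_full, model_transforms, pack_gng_sessions,
    trialwise_choice_probs,
)
from .hierarchical import EmbeddedDraws, McmcConfig, fit_embedded_hierarchical
from .reliability import PairedMeasures, pearson


@dataclass
class EmbeddedSpec:
    """What to fit jointly and how."""

    model: str = "rw_go_pav_split"  # go/no-go family id or "ddm4"
    lkj_eta: float = 1.0
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def __post_init__(self):
        if self.lkj_eta <= 0:
            raise ValueError("LKJ shape eta must be > 0")
        if self.lkj_eta != 1.0:
            raise NotImplementedError(
                "only the uniform correlation prior (eta = 1) is implemented")


@dataclass
class EmbeddedResult:
    """Posterior summaries of the per-parameter cross-session correlations."""

    model: str
    param_names: list[str]
    r_mean: dict[str, float]
    r_ci_low: dict[str, float]
    r_ci_high: dict[str, float]
    draws: EmbeddedDraws
    diagnostics: dict

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"parameter": p, "r_mean": self.r_mean[p],
             "r_ci_low": self.r_ci_low[p], "r_ci_high": self.r_ci_high[p]}
            for p in self.param_names
        ])


def _gng_session_loglik_fns(sessions_by_no: dict[int, list[SubjectSessionData]],
                            model_id: str):
    fns = []
    for sess_no in (1, 2):
        _, cues, choices, rewards = pack_gng_sessions(sessions_by_no[sess_no])

        def loglik(native, cues=cues, choices=choices, rewards=rewards):
            full = expand_to_full(model_id, native)
            probs = trialwise_choice_probs(full, cues, choices, rewards)
            return np.log(np.maximum(probs, 1e-300)).sum(axis=1)

        fns.append(loglik)
    return fns, model_transforms(model_id)


def _ddm_session_loglik_fns(sessions_by_no: dict[int, list[SubjectSessionData]]):
    fns = []
    for sess_no in (1, 2):
        rt, upper, idx, n = _packed_mid_trials(sessions_by_no[sess_no])
        fns.append(_ddm_loglik_closure(rt, upper, idx, n))
    return fns, ddm_transforms()


def _matched_sessions(cohort: CohortData, task: str
                      ) -> dict[int, list[SubjectSessionData]]:
    by_no = {s: cohort.sessions(task=task, session=s) for s in (1, 2)}
    ids = [sorted((d.subject_id for d in by_no[s]), key=str) for s in (1, 2)]
    if ids[0] != ids[1] or not ids[0]:
        missing = set(ids[0]).symmetric_difference(ids[1])
        raise ValueError(f"subjects missing a session: {sorted(missing, key=str)}")
    for s in (1, 2):
        by_no[s] = sorted(by_no[s], key=lambda d: str(d.subject_id))
    return by_no


def fit_embedded(cohort: CohortData, spec: EmbeddedSpec) -> EmbeddedResult:
    """Joint two-session fit returning cross-session correlation posteriors."""
    task = "ambiguous_midpoint" if spec.model == "ddm4" else "gonogo"
    by_no = _matched_sessions(cohort, task)
    if spec.model == "ddm4":
        fns, transforms = _ddm_session_loglik_fns(by_no)
        init_mu = np.array([0.3, 0.0, 0.0, np.log(0.15)])
    else:
        fns, transforms = _gng_session_loglik_fns(by_no, spec.model)
        init_mu = None

    draws = fit_embedded_hierarchical(
        fns, transforms, len(by_no[1]), spec.mcmc, init_mu=init_mu)
    names = draws.param_names
    flat_r = draws.r.reshape(-1, len(names))
    r_mean = {p: float(flat_r[:, j].mean()) for j, p in enumerate(names)}
    lo = {p: float(np.quantile(flat_r[:, j], 0.025))
          for j, p in enumerate(names)}
    hi = {p: float(np.quantile(flat_r[:, j], 0.975))
          for j, p in enumerate(names)}
    return EmbeddedResult(
        model=spec.model, param_names=names, r_mean=r_mean,
        r_ci_low=lo, r_ci_high=hi, draws=draws,
        diagnostics=draws.diagnostics,
    )


def compare_two_stage_vs_embedded(
    cohort: CohortData,
    spec: EmbeddedSpec,
    fit_fn=None,
) -> pd.DataFrame:
    """Two-stage Pearson on point estimates vs embedded posterior r.

    Runs the per-session hierarchical fit twice (or uses ``fit_fn(sessions)``
    when supplied, e.g. with shortened chains), Pearson-correlates the
    native-scale subject posterior means, then fits the embedded model and
    tabulates both estimates with their intervals per parameter.
    """
    task = "ambiguous_midpoint" if spec.model == "ddm4" else "gonogo"
    by_no = _matched_sessions(cohort, task)

    if fit_fn is None:
        if spec.model == "ddm4":
            from .ddm_model import fit_hierarchical_ddm as fit_fn
        else:
            from .gonogo_model import fit_hierarchical_gng as _fit

            def fit_fn(sessions):
                return _fit(sessions, model_id=spec.model, mcmc=spec.mcmc)
    fits = {s: fit_fn(by_no[s]) for s in (1, 2)}
    embedded = fit_embedded(cohort, spec)

    rows = []
    cols = {s: fits[s].subject_means.set_index("subject") for s in (1, 2)}
    cols[2] = cols[2].reindex(cols[1].index)
    for p in embedded.param_names:
        pm = PairedMeasures(tuple(cols[1].index),
                            cols[1][p].to_numpy(),
                            cols[2][p].to_numpy())
        est = pearson(pm)
        rows.append({
            "parameter": p,
            "two_stage_r": est.coefficient,
            "two_stage_ci_low": est.ci_low,
            "two_stage_ci_high": est.ci_high,
            "embedded_r": embedded.r_mean[p],
            "embedded_ci_low": embedded.r_ci_low[p],
            "embedded_ci_high": embedded.r_ci_high[p],
        })
    return pd.DataFrame(rows)
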