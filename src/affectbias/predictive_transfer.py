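"""Cross-session posterior-predictive transfer of fitted parameters.

For each subject the mean trialwise likelihood of the choices actually made
in a target session is computed under parameters taken from a source
session — their own subject-level posterior means or the group mean — in
all four direction combinations (s1->s2, s2->s1 and the own-session
baselines).  For the go/no-go model the latent state evolves along the
target session's observed choices and outcomes; for the diffusion model the
likelihood is the choice probability of the observed key on responded
midpoint trials (marginal over RT), so chance is exactly 0.5 in both cases.
One-sample t-tests against chance and paired t-tests of individual minus
group-mean likelihoods quantify predictive transfer and shrinkage; p-values
are reported uncorrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FitResult, SubjectSessionData
from .ddm_model import DDMParams, choice_probability
from .gonogo_model import (
    GNGParams, pack_gng_sessions, trialwise_choice_probs,
)

DIRECTIONS = ("s1s2", "s2s1", "s1s1", "s2s2")


def transfer_likelihood(params: GNGParams | DDMParams,
                        session: SubjectSessionData) -> float:
    """Mean trialwise likelihood of one session's observed choices."""
    if len(session.trials) == 0:
        raise ValueError("empty target session")
    if isinstance(params, GNGParams):
        _, cues, choices, rewards = pack_gng_sessions([session])
        probs = trialwise_choice_probs(params.as_array()[None, :],
                                       cues, choices, rewards)
        return float(probs.mean())
    df = session.trials
    mid = df[(df["condition"] == "mid")
             & (df["choice"].isin(["key_low", "key_high"]))]
    if len(mid) == 0:
        raise ValueError("no responded midpoint trials in target session")
    p_up = choice_probability(params)
    obs = (mid["choice"] == "key_high").to_numpy()
    return float(np.where(obs, p_up, 1.0 - p_up).mean())


def group_mean_params(fit: FitResult, force: bool = False) -> dict[str, float]:
    """Native-scale mean across subjects of subject-level posterior means."""
    fit.require_converged(force=force)
    cols = [c for c in fit.subject_means.columns if c != "subject"]
    return {c: float(fit.subject_means[c].mean()) for c in cols}


def _params_from_row(task: str, row: dict) -> GNGParams | DDMParams:
    if task == "gonogo":
        return GNGParams(**{k: row[k] for k in row if k != "subject"})
    return DDMParams(alpha=row["alpha"], beta=row["beta"],
                     delta=row["delta"], tau=row["tau"])


def transfer_table(fits: dict[int, FitResult],
                   sessions: dict[int, list[SubjectSessionData]],
                   task: str, force: bool = False) -> pd.DataFrame:
    """TransferResult rows for every subject x direction x parameter source.

    ``fits`` and ``sessions`` map session number (1, 2) to that session's
    fit and per-subject data; subjects must match across sessions.
    """
    means = {s: fits[s].subject_means.set_index("subject") for s in (1, 2)}
    group = {s: group_mean_params(fits[s], force=force) for s in (1, 2)}
    data = {s: {d.subject_id: d for d in sessions[s]} for s in (1, 2)}
    subjects = sorted(data[1], key=str)
    if sorted(data[2], key=str) != subjects:
        raise ValueError("subjects differ between sessions")

    rows = []
    for direction in DIRECTIONS:
        src, tgt = int(direction[1]), int(direction[3])
        for subj in subjects:
            own = means[src].loc[subj].to_dict()
            for source, row in (("individual", own), ("group_mean", group[src])):
                ll = transfer_likelihood(_params_from_row(task, row),
                                         data[tgt][subj])
                rows.append({
                    "subject": subj, "direction": direction,
                    "parameter_source": source,
                    "mean_trialwise_likelihood": ll,
                })
    return pd.DataFrame(rows)


def transfer_tests(results: pd.DataFrame) -> pd.DataFrame:
    """t-tests versus chance (0.5) and individual-vs-group-mean, per direction."""
    if results.empty:
        raise ValueError("empty transfer table")
    rows = []
    for direction, grp in results.groupby("direction"):
        ind = grp[grp["parameter_source"] == "individual"] \
            .set_index("subject")["mean_trialwise_likelihood"]
        gm = grp[grp["parameter_source"] == "group_mean"] \
            .set_index("subject")["mean_trialwise_likelihood"]
        if len(ind) < 3 or len(gm) < 3:
            raise ValueError(f"direction {direction}: fewer than 3 subjects")
        if np.allclose(ind, 0.5):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(ind, 0.5)
        rows.append({"direction": direction, "test": "individual_vs_chance",
                     "t": float(t), "df": len(ind) - 1, "p": float(p),
                     "mean": float(ind.mean())})
        diff = (ind - gm.reindex(ind.index)).to_numpy()
        if np.allclose(diff, 0.0):
            t2, p2 = 0.0, 1.0
        else:
            t2, p2 = stats.ttest_1samp(diff, 0.0)
        rows.append({"direction": direction,
                     "test": "individual_vs_group_mean",
                     "t": float(t2), "df": len(diff) - 1, "p": float(p2),
                     "mean": float(diff.mean())})
    return pd.DataFrame(rows)
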