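"""Summary-statistic bias indices and participant-exclusion rules.

Five indices are computed per subject-session: accuracy on each of the
four go/no-go cue types (go responses on go cues, withheld responses on
no-go cues; a non-response counts as a no-go choice since the task's action
space is respond/withhold), and p(high|mid) — the proportion of responded
midpoint trials answered with the high-reward key (1 - p(high|mid) is the
negative-bias reading).

Exclusion mirrors the study's screening: zero go-to-win accuracy in either
session, no responses at all in a task, a single response key throughout
the ambiguous-midpoint task, never choosing the high-reward key on midpoint
trials, or duplicated trial records.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import CohortData, SubjectSessionData
from .task_designs import CUE_TYPES, GO_CUES

EXCLUSION_REASONS = (
    "zero_go_to_win_accuracy",
    "no_responses_any_task",
    "single_key_am",
    "never_high_on_mid",
    "duplicate_trials",
)


def condition_accuracies(session: SubjectSessionData) -> dict[str, float]:
    """Accuracy per cue type for one go/no-go session.

    Go-cue accuracy counts go responses; no-go-cue accuracy counts withheld
    responses.  Denominators are the per-cue trial counts.
    """
    df = session.trials
    out: dict[str, float] = {}
    for cue in CUE_TYPES:
        sub = df[df["condition"] == cue]
        if len(sub) == 0:
            raise ValueError(f"session has no {cue!r} trials")
        went = (sub["choice"] == "go").to_numpy()
        acc = went.mean() if cue in GO_CUES else 1.0 - went.mean()
        out[f"acc_{cue}"] = float(acc)
        out[f"n_{cue}"] = int(len(sub))
    return out


def p_high_given_mid(session: SubjectSessionData) -> tuple[float, int]:
    """(p(high|mid), n responded mid trials); NaN when nothing responded.

    Non-responses are excluded from the denominator; an all-timeout session
    yields (nan, 0) rather than 0 so callers can flag it as undefined.
    """
    df = session.trials
    mid = df[df["condition"] == "mid"]
    if len(mid) == 0:
        raise ValueError("session has no midpoint trials")
    responded = mid[mid["choice"].isin(["key_low", "key_high"])]
    if len(responded) == 0:
        return float("nan"), 0
    return float((responded["choice"] == "key_high").mean()), len(responded)


def session_summaries(cohort: CohortData) -> pd.DataFrame:
    """All five indices (plus denominators) per subject-session."""
    rows: dict[tuple, dict] = {}
    for s in cohort.sessions(task="gonogo"):
        rows.setdefault((s.subject_id, s.session), {
            "subject": s.subject_id, "session": s.session,
        }).update(condition_accuracies(s))
    for s in cohort.sessions(task="ambiguous_midpoint"):
        p, n = p_high_given_mid(s)
        rows.setdefault((s.subject_id, s.session), {
            "subject": s.subject_id, "session": s.session,
        }).update({"p_high_mid": p, "n_mid_responded": n})
    return pd.DataFrame(sorted(rows.values(),
                               key=lambda r: (str(r["subject"]), r["session"])))


@dataclass(frozen=True)
class ExclusionReport:
    subject_id: object
    excluded: bool
    reasons: tuple[str, ...]

    def __post_init__(self):
        assert self.excluded == bool(self.reasons)


def _session_responses(s: SubjectSessionData) -> pd.Series:
    if s.task == "gonogo":
        return s.trials["choice"].isin(["go"])
    return s.trials["choice"].isin(["key_low", "key_high"])


def apply_exclusions(cohort: CohortData
                     ) -> tuple[CohortData, list[ExclusionReport]]:
    """Drop subjects for whom any screening rule fires in either session."""
    reasons: dict[object, set[str]] = {s: set() for s in cohort.subject_ids()}

    dup = cohort.trials.duplicated(subset=["subject", "session", "task", "trial"])
    for subj in cohort.trials.loc[dup, "subject"].unique():
        reasons[subj].add("duplicate_trials")

    for s in cohort.sessions():
        subj = s.subject_id
        if not _session_responses(s).any():
            reasons[subj].add("no_responses_any_task")
        if s.task == "gonogo":
            gtw = s.trials[s.trials["condition"] == "go_to_win"]
            if len(gtw) and not (gtw["choice"] == "go").any():
                reasons[subj].add("zero_go_to_win_accuracy")
        else:
            resp = s.trials[s.trials["choice"].isin(["key_low", "key_high"])]
            if len(resp) and resp["choice"].nunique() == 1:
                reasons[subj].add("single_key_am")
            mid = s.trials[(s.trials["condition"] == "mid")
                           & s.trials["choice"].isin(["key_low", "key_high"])]
            if len(mid) and not (mid["choice"] == "key_high").any():
                reasons[subj].add("never_high_on_mid")

    reports = [
        ExclusionReport(subj, bool(rs), tuple(sorted(rs)))
        for subj, rs in sorted(reasons.items(), key=lambda kv: str(kv[0]))
    ]
    excluded = {r.subject_id for r in reports if r.excluded}
    kept = cohort.trials[~cohort.trials["subject"].isin(excluded)]
    true_params = cohort.true_params
    if true_params is not None:
        true_params = true_params[~true_params["subject"].isin(excluded)]
    filtered = CohortData(trials=kept.reset_index(drop=True),
                          true_params=true_params,
                          manifest={**cohort.manifest,
                                    "n_excluded": len(excluded)})
    return filtered, reports


def exclusion_frame(reports: list[ExclusionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject": r.subject_id, "excluded": r.excluded,
          "reasons": ";".join(r.reasons)} for r in reports]
    )
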