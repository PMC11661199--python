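"""Shared in-memory containers for trial data and fit results."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical column order of the trials table
TRIAL_COLUMNS = [
    "subject", "session", "task", "trial", "condition", "choice", "rt", "outcome",
]


@dataclass
class SubjectSessionData:
    """One subject-session's ordered trial records.

    ``trials`` has columns trial, condition, choice, rt, outcome; rt is NaN
    for the go/no-go task (choices only) and for non-responses.
    """

    subject_id: int | str
    session: int
    task: str  # {"gonogo", "ambiguous_midpoint"}
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.trials = self.trials.sort_values("trial").reset_index(drop=True)


@dataclass
class CohortData:
    """All subject-session records of a simulated or observed cohort."""

    trials: pd.DataFrame  # TRIAL_COLUMNS
    true_params: pd.DataFrame | None = None  # subject, parameter, session1, session2
    manifest: dict = field(default_factory=dict)

    def sessions(self, task: str | None = None, session: int | None = None
                 ) -> list[SubjectSessionData]:
        df = self.trials
        if task is not None:
            df = df[df["task"] == task]
        if session is not None:
            df = df[df["session"] == session]
        out = []
        for (subj, sess), grp in df.groupby(["subject", "session"], sort=True):
            out.append(SubjectSessionData(
                subj, int(sess), grp["task"].iloc[0],
                grp[["trial", "condition", "choice", "rt", "outcome"]].copy(),
            ))
        return out

    def subject_ids(self) -> list:
        return sorted(self.trials["subject"].unique().tolist())


def data_hash(sessions: list[SubjectSessionData]) -> str:
    """Stable hash of a list of subject-sessions, for fit-comparison checks."""
    h = hashlib.sha256()
    for s in sorted(sessions, key=lambda s: (str(s.subject_id), s.session)):
        h.update(str((s.subject_id, s.session, s.task)).encode())
        h.update(s.trials.to_csv(index=False).encode())
    return h.hexdigest()[:16]


@dataclass
class FitResult:
    """Posterior draws and summaries from a hierarchical fit.

    ``draws`` maps names ("mu", "sigma", "theta") to arrays with leading
    (chain, draw) axes; theta draws are on the unconstrained scale.
    ``subject_means`` holds native-scale posterior means, one row per subject.
    """

    model_id: str
    param_names: list[str]
    subject_ids: list
    draws: dict[str, np.ndarray]
    subject_means: pd.DataFrame
    group_summary: pd.DataFrame
    diagnostics: dict
    data_hash: str
    pointwise_loglik: np.ndarray | None = None  # (chain, draw, n_points)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def require_converged(self, force: bool = False) -> None:
        if not self.converged and not force:
            raise RuntimeError(
                f"fit of {self.model_id} did not converge "
                f"(max split-Rhat {self.diagnostics.get('max_rhat'):.3f}); "
                "pass force=True to use it anyway"
            )

    def save(self, directory: str | Path) -> None:
        """Persist draws (long CSV), subject means, and a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for name in ("mu", "sigma"):
            arr = self.draws[name]
            for p, pname in enumerate(self.param_names):
                for c in range(arr.shape[0]):
                    for d in range(arr.shape[1]):
                        rows.append((c, d, f"{name}_{pname}", arr[c, d, p]))
        pd.DataFrame(rows, columns=["chain", "draw", "parameter", "value"]).to_csv(
            directory / "draws.csv", index=False)
        self.subject_means.to_csv(directory / "subject_means.csv", index=False)
        manifest = {
            "model_id": self.model_id,
            "param_names": self.param_names,
            "data_hash": self.data_hash,
            "diagnostics": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.diagnostics.items()
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
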