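"""Readers and writers for the trial-level CSV interchange format.

One row per trial with columns subject, session, task, trial, condition,
choice, rt, outcome.  RT is in seconds and may be empty for go/no-go rows
(a choices-only task); sessions are labelled 1 and 2; trial indices are
0-based within a subject-session.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import TRIAL_COLUMNS, CohortData


def write_trials(cohort: CohortData, path: str | Path) -> None:
    """Write the trials table; sidecar files carry truth and manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.trials[TRIAL_COLUMNS].to_csv(path, index=False)
    if cohort.true_params is not None:
        cohort.true_params.to_csv(
            path.with_name(path.stem + "_true_params.csv"), index=False)
    if cohort.manifest:
        path.with_name(path.stem + "_manifest.json").write_text(
            json.dumps(cohort.manifest, indent=2, default=str))


def read_trials(path: str | Path) -> CohortData:
    """Read a trials CSV, validating schema and key uniqueness."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"condition": str, "choice": str,
                                  "outcome": str, "task": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials file {path} is missing columns: {missing}")

    bad_rows = []
    for col in ("subject", "session", "trial"):
        bad = df[df[col].isna()]
        bad_rows.extend((int(i) + 2, col) for i in bad.index)  # 1-based + header
    if bad_rows:
        raise ValueError(f"malformed rows (line, column): {bad_rows[:10]}")

    dup = df.duplicated(subset=["subject", "session", "task", "trial"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValueError(
            f"duplicate (subject, session, task, trial) keys at lines {lines}")

    gng_rt = df.loc[(df["task"] == "ambiguous_midpoint")
                    & df["choice"].isin(["key_low", "key_high"]), "rt"]
    if gng_rt.isna().any():
        n = int(gng_rt.isna().sum())
        raise ValueError(
            f"{n} responded ambiguous-midpoint rows lack an RT value")

    df["session"] = df["session"].astype(int)
    df["trial"] = df["trial"].astype(int)
    df["rt"] = pd.to_numeric(df["rt"], errors="coerce")

    true_params = None
    tp_path = path.with_name(path.stem + "_true_params.csv")
    if tp_path.exists():
        true_params = pd.read_csv(tp_path)
    manifest = {}
    mf_path = path.with_name(path.stem + "_manifest.json")
    if mf_path.exists():
        manifest = json.loads(mf_path.read_text())
    return CohortData(trials=df, true_params=true_params, manifest=manifest)
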