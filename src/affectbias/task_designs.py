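"""Trial schedules and feedback rules for the two affective-bias tasks.

Two tasks are implemented:

* an orthogonalized **go/no-go** task with four interleaved cue types
  crossing action (go vs no-go) with valence (win vs avoid-loss), 40 trials
  per cue and 80% veridical feedback by default;
* an **ambiguous-midpoint** task in which small and large circles are
  deterministically mapped to a low ($1) and high ($4) reward key, and a
  midpoint circle is rewarded on either key 50% of the time.

Schedules are generated deterministically from a seed; feedback operators are
pure functions of the trial record and the action taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Cue order is load-bearing: indices < 2 are win cues, even indices are
# go cues.  Model code relies on this mapping.
CUE_TYPES = ("go_to_win", "nogo_to_win", "go_to_avoid", "nogo_to_avoid")
WIN_CUES = frozenset({"go_to_win", "nogo_to_win"})
GO_CUES = frozenset({"go_to_win", "go_to_avoid"})

CIRCLE_SIZES = ("small", "mid", "large")

#: reward magnitude associated with each response key ($)
KEY_MAGNITUDE = {"key_low": 1, "key_high": 4}
#: deterministic key mapping learnt in training
TRAINED_KEY = {"small": "key_low", "large": "key_high"}


def correct_action(cue_type: str) -> str:
    """The response that tends to produce the better outcome for a cue."""
    if cue_type not in CUE_TYPES:
        raise ValueError(f"unknown cue type: {cue_type!r}")
    return "go" if cue_type in GO_CUES else "nogo"


@dataclass(frozen=True)
class GoNogoTrial:
    cue_type: str
    veridical: bool
    circle_side: str  # {"left", "right"}; cosmetic, no effect on outcomes

    @property
    def correct_action(self) -> str:
        return correct_action(self.cue_type)


@dataclass(frozen=True)
class GoNogoSchedule:
    trials: tuple[GoNogoTrial, ...]
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class AMTrial:
    circle_size: str  # {"small", "mid", "large"}
    rewarded_key: str  # the key that yields reward on this trial
    phase: str = "main"  # {"training", "main"}

    @property
    def reward_magnitude(self) -> int:
        return KEY_MAGNITUDE[self.rewarded_key]


@dataclass(frozen=True)
class AMSchedule:
    training_trials: tuple[AMTrial, ...]
    main_trials: tuple[AMTrial, ...]
    seed: int = field(default=0)


def generate_gonogo_schedule(
    seed: int,
    n_per_cue: int = 40,
    veridical_prop: float = 0.8,
    iid_feedback: bool = False,
) -> GoNogoSchedule:
    """Generate a seeded go/no-go schedule.

    By default each of the four cues appears exactly ``n_per_cue`` times in a
    seeded random interleaving, and within each cue exactly
    ``round(veridical_prop * n_per_cue)`` trials deliver veridical feedback
    (the rest are misleading).  With ``iid_feedback=True`` the veridical flag
    is instead drawn i.i.d. Bernoulli(``veridical_prop``) per trial.
    """
    if n_per_cue < 1:
        raise ValueError("n_per_cue must be >= 1")
    if not (0.0 < veridical_prop <= 1.0):
        raise ValueError("veridical_prop must be in (0, 1]")

    rng = np.random.default_rng(seed)
    exact = veridical_prop * n_per_cue
    n_veridical = int(round(exact))
    if abs(exact - n_veridical) > 1e-9:
        logger.info(
            "veridical_prop * n_per_cue = %.3f is not an integer; "
            "rounding to %d veridical trials per cue", exact, n_veridical
        )

    trials: list[GoNogoTrial] = []
    for cue in CUE_TYPES:
        if iid_feedback:
            flags = rng.random(n_per_cue) < veridical_prop
        else:
            flags = np.zeros(n_per_cue, dtype=bool)
            flags[:n_veridical] = True
            rng.shuffle(flags)
        for flag in flags:
            side = "left" if rng.random() < 0.5 else "right"
            trials.append(GoNogoTrial(cue, bool(flag), side))

    order = rng.permutation(len(trials))
    return GoNogoSchedule(tuple(trials[i] for i in order), seed=seed)


def gonogo_feedback(trial: GoNogoTrial, action: str) -> int:
    """Outcome in points (+10 / 0 / -10) for an action on a go/no-go trial.

    Win cues pay {+10, 0}; avoid cues pay {0, -10}.  The better outcome of
    the pair is delivered when the response is correct and feedback is
    veridical, or when the response is incorrect and feedback is misleading.
    """
    if action not in ("go", "nogo"):
        raise ValueError(f"invalid action: {action!r}")
    win_cue = trial.cue_type in WIN_CUES
    better_delivered = (action == trial.correct_action) == trial.veridical
    if win_cue:
        return 10 if better_delivered else 0
    return 0 if better_delivered else -10


def generate_am_schedule(
    seed: int, n_training: int = 20, n_per_size: int = 40
) -> AMSchedule:
    """Generate a seeded ambiguous-midpoint schedule.

    The training phase interleaves small and large circles (half each) with
    fully deterministic reward.  The main phase contains ``n_per_size``
    trials of each circle size; midpoint trials reward the high-reward key on
    exactly half of them.  The schedule is intended to be shared across
    subjects (the task uses a single randomized order for everyone).
    """
    if n_training < 1 or n_per_size < 1:
        raise ValueError("trial counts must be >= 1")
    if n_per_size % 2 != 0:
        raise ValueError(
            "n_per_size must be even so midpoint trials split 50/50"
        )

    rng = np.random.default_rng(seed)

    half = n_training // 2
    train_sizes = ["small"] * half + ["large"] * (n_training - half)
    rng.shuffle(train_sizes)
    training = tuple(
        AMTrial(sz, TRAINED_KEY[sz], phase="training") for sz in train_sizes
    )

    main: list[AMTrial] = []
    for sz in ("small", "large"):
        main.extend(AMTrial(sz, TRAINED_KEY[sz]) for _ in range(n_per_size))
    mid_keys = ["key_high"] * (n_per_size // 2) + ["key_low"] * (n_per_size // 2)
    rng.shuffle(mid_keys)
    main.extend(AMTrial("mid", k) for k in mid_keys)
    order = rng.permutation(len(main))
    return AMSchedule(training, tuple(main[i] for i in order), seed=seed)


def am_feedback(trial: AMTrial, pressed_key: str) -> str:
    """Outcome of a key press on an ambiguous-midpoint trial.

    Returns ``"win_4"`` or ``"win_1"`` when the pressed key is the rewarded
    one (magnitude follows the key's trained association), otherwise
    ``"timeout_incorrect"``.
    """
    if pressed_key not in KEY_MAGNITUDE:
        raise ValueError(f"invalid key: {pressed_key!r}")
    if pressed_key == trial.rewarded_key:
        return f"win_{trial.reward_magnitude}"
    return "timeout_incorrect"


def gonogo_schedule_frame(schedule: GoNogoSchedule) -> pd.DataFrame:
    """Serialize a go/no-go schedule to the standard schedule table."""
    rows = [
        {
            "task": "gonogo",
            "trial_index": i,
            "condition": t.cue_type,
            "correct_action_or_rewarded_key": t.correct_action,
            "veridical": t.veridical,
            "extra": t.circle_side,
        }
        for i, t in enumerate(schedule.trials)
    ]
    return pd.DataFrame(rows)


def am_schedule_frame(schedule: AMSchedule) -> pd.DataFrame:
    """Serialize an ambiguous-midpoint schedule (training then main)."""
    rows = []
    for i, t in enumerate(schedule.training_trials + schedule.main_trials):
        rows.append(
            {
                "task": "ambiguous_midpoint",
                "trial_index": i,
                "condition": (
                    f"train_{t.circle_size}" if t.phase == "training"
                    else t.circle_size
                ),
                "correct_action_or_rewarded_key": t.rewarded_key,
                "veridical": True,
                "extra": t.reward_magnitude,
            }
        )
    return pd.DataFrame(rows)
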