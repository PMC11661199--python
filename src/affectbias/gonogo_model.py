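"""Pavlovian-bias reinforcement-learning models of the go/no-go task.

The full (winning) model has seven parameters: a learning rate ``epsilon``,
a constant go bias ``b``, separate Pavlovian approach and avoid biases
coupling stimulus value to action on win and avoid cues, separate reward and
punishment sensitivities scaling the outcome, and a lapse ``xi`` mixing
uniform random responding into the value-based choice rule.  Reduced family
members share or drop terms (see ``MODEL_FAMILY``).

Action weights on each trial are

    W(go)   = Q(go, cue) + b + pi_cue * V(cue)
    W(nogo) = Q(nogo, cue)

with ``pi_cue`` the approach bias on win cues and the avoid bias on avoid
cues, and

    p(go) = xi/2 + (1 - xi) * logistic(W(go) - W(nogo)).

After feedback r in {-1, 0, +1} (points / 10), the taken action's Q value
and the stimulus value V update by a delta rule on the sensitivity-scaled
outcome ``u`` (``rho_rew * r`` for rewards, ``rho_pun * r`` for losses):

    Q(a, cue) += epsilon * (u - Q(a, cue))
    V(cue)    += epsilon * (u - V(cue))

Hierarchical fitting uses the package's Metropolis-within-Gibbs engine with
probit maps for epsilon and xi and log maps for the sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FitResult, SubjectSessionData, data_hash
from .hierarchical import McmcConfig, fit_hierarchical
from .task_designs import CUE_TYPES
from .transforms import ParamTransform

FULL_PARAMS = (
    "epsilon", "b", "pi_approach", "pi_avoid", "rho_rew", "rho_pun", "xi",
)

#: model family, simplest to richest; "rw_go_pav_split" is the winning model
MODEL_FAMILY: dict[str, tuple[str, ...]] = {
    "rw": ("epsilon", "rho", "xi"),
    "rw_go": ("epsilon", "rho", "b", "xi"),
    "rw_go_pav": ("epsilon", "rho", "b", "pi", "xi"),
    "rw_go_pav_sens": ("epsilon", "rho_rew", "rho_pun", "b", "pi", "xi"),
    "rw_go_pav_split": (
        "epsilon", "rho_rew", "rho_pun", "b", "pi_approach", "pi_avoid", "xi",
    ),
}

_TRANSFORM_KIND = {
    "epsilon": "probit", "xi": "probit",
    "rho": "log", "rho_rew": "log", "rho_pun": "log",
    "b": "identity", "pi": "identity",
    "pi_approach": "identity", "pi_avoid": "identity",
}


def model_transforms(model_id: str) -> list[ParamTransform]:
    try:
        names = MODEL_FAMILY[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}; "
                         f"choose from {sorted(MODEL_FAMILY)}") from None
    return [ParamTransform(n, _TRANSFORM_KIND[n]) for n in names]


def expand_to_full(model_id: str, free: np.ndarray) -> np.ndarray:
    """Map a native (n, P_free) matrix onto the full 7-parameter layout."""
    names = MODEL_FAMILY[model_id]
    free = np.atleast_2d(free)
    col = {n: free[:, j] for j, n in enumerate(names)}
    n = free.shape[0]
    zeros = np.zeros(n)
    rho_rew = col.get("rho_rew", col.get("rho"))
    rho_pun = col.get("rho_pun", col.get("rho"))
    pi_app = col.get("pi_approach", col.get("pi", zeros))
    pi_av = col.get("pi_avoid", col.get("pi", zeros))
    return np.column_stack([
        col["epsilon"], col.get("b", zeros), pi_app, pi_av,
        rho_rew, rho_pun, col["xi"],
    ])


@dataclass
class GNGParams:
    """Native-scale parameter vector of the full model."""

    epsilon: float
    b: float = 0.0
    pi_approach: float = 0.0
    pi_avoid: float = 0.0
    rho_rew: float = 1.0
    rho_pun: float = 1.0
    xi: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.epsilon, self.b, self.pi_approach,
                         self.pi_avoid, self.rho_rew, self.rho_pun, self.xi])

    @classmethod
    def from_array(cls, a) -> "GNGParams":
        return cls(*[float(x) for x in a])


@dataclass
class GNGLatentState:
    """Q values per (action, cue) and Pavlovian stimulus values V per cue."""

    Q: np.ndarray = field(default_factory=lambda: np.zeros((2, 4)))
    V: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def copy(self) -> "GNGLatentState":
        return GNGLatentState(self.Q.copy(), self.V.copy())


def _cue_index(cue) -> int:
    return CUE_TYPES.index(cue) if isinstance(cue, str) else int(cue)


def p_go(state: GNGLatentState, params: GNGParams, cue) -> float:
    """Probability of a go response for the current latent state."""
    c = _cue_index(cue)
    pi = params.pi_approach if c < 2 else params.pi_avoid
    w = state.Q[1, c] + params.b + pi * state.V[c] - state.Q[0, c]
    return params.xi / 2.0 + (1.0 - params.xi) / (1.0 + np.exp(-w))


def update_state(state: GNGLatentState, params: GNGParams, cue,
                 action: str | int, outcome: int) -> GNGLatentState:
    """Delta-rule update after observing feedback; returns a new state."""
    c = _cue_index(cue)
    a = 1 if action in (1, "go") else 0
    r = int(outcome) // 10
    if r > 0:
        u = params.rho_rew * r
    elif r < 0:
        u = params.rho_pun * r
    else:
        u = 0.0
    new = state.copy()
    new.Q[a, c] += params.epsilon * (u - new.Q[a, c])
    new.V[c] += params.epsilon * (u - new.V[c])
    return new


def session_loglik(params: GNGParams, session: SubjectSessionData) -> float:
    """Log-likelihood of one session's choices under the model."""
    state = GNGLatentState()
    total = 0.0
    for row in session.trials.itertuples(index=False):
        if row.choice not in ("go", "nogo"):
            raise ValueError(f"invalid go/no-go choice code: {row.choice!r}")
        pg = p_go(state, params, row.condition)
        p = pg if row.choice == "go" else 1.0 - pg
        total += np.log(max(p, 1e-300))
        state = update_state(state, params, row.condition, row.choice,
                             int(float(row.outcome)))
    return float(total)


# ---------------------------------------------------------------------------
# vectorised likelihood kernel (numba when available)
# ---------------------------------------------------------------------------

def _trial_probs_py(params7, cues, choices, rewards):
    n, T = cues.shape
    probs = np.empty((n, T))
    for i in range(n):
        eps, b, pia, piv, rr, rp, xi = params7[i]
        Q = np.zeros((2, 4))
        V = np.zeros(4)
        for t in range(T):
            cue = cues[i, t]
            pi = pia if cue < 2 else piv
            w = Q[1, cue] + b + pi * V[cue] - Q[0, cue]
            pgo = xi * 0.5 + (1.0 - xi) / (1.0 + np.exp(-w))
            a = choices[i, t]
            probs[i, t] = pgo if a == 1 else 1.0 - pgo
            r = rewards[i, t]
            if r > 0:
                u = rr * r
            elif r < 0:
                u = rp * r
            else:
                u = 0.0
            Q[a, cue] += eps * (u - Q[a, cue])
            V[cue] += eps * (u - V[cue])
    return probs


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=False)
    def _trial_probs_nb(params7, cues, choices, rewards):  # noqa: D103
        n, T = cues.shape
        probs = np.empty((n, T))
        for i in range(n):
            eps = params7[i, 0]
            b = params7[i, 1]
            pia = params7[i, 2]
            piv = params7[i, 3]
            rr = params7[i, 4]
            rp = params7[i, 5]
            xi = params7[i, 6]
            Q = np.zeros((2, 4))
            V = np.zeros(4)
            for t in range(T):
                cue = cues[i, t]
                pi = pia if cue < 2 else piv
                w = Q[1, cue] + b + pi * V[cue] - Q[0, cue]
                pgo = xi * 0.5 + (1.0 - xi) / (1.0 + np.exp(-w))
                a = choices[i, t]
                if a == 1:
                    probs[i, t] = pgo
                else:
                    probs[i, t] = 1.0 - pgo
                r = rewards[i, t]
                if r > 0:
                    u = rr * r
                elif r < 0:
                    u = rp * r
                else:
                    u = 0.0
                Q[a, cue] += eps * (u - Q[a, cue])
                V[cue] += eps * (u - V[cue])
        return probs

    _trial_probs = _trial_probs_nb
except ImportError:  # pragma: no cover
    _trial_probs = _trial_probs_py


def trialwise_choice_probs(params7: np.ndarray, cues: np.ndarray,
                           choices: np.ndarray, rewards: np.ndarray
                           ) -> np.ndarray:
    """p(observed choice) per trial for each subject, (n, T)."""
    return _trial_probs(
        np.ascontiguousarray(np.atleast_2d(params7), dtype=np.float64),
        np.ascontiguousarray(cues, dtype=np.int64),
        np.ascontiguousarray(choices, dtype=np.int64),
        np.ascontiguousarray(rewards, dtype=np.int64),
    )


def pack_gng_sessions(sessions: list[SubjectSessionData]
                      ) -> tuple[list, np.ndarray, np.ndarray, np.ndarray]:
    """Pack equal-length sessions into (ids, cues, choices, rewards) arrays."""
    lengths = {len(s.trials) for s in sessions}
    if len(lengths) != 1:
        raise ValueError(f"sessions have unequal trial counts: {lengths}")
    ids, cues, choices, rewards = [], [], [], []
    for s in sessions:
        ids.append(s.subject_id)
        cues.append([CUE_TYPES.index(c) for c in s.trials["condition"]])
        choices.append([1 if ch == "go" else 0 for ch in s.trials["choice"]])
        rewards.append([int(float(o)) // 10 for o in s.trials["outcome"]])
    return (ids, np.array(cues, dtype=np.int64),
            np.array(choices, dtype=np.int64),
            np.array(rewards, dtype=np.int64))


def fit_hierarchical_gng(
    sessions: list[SubjectSessionData],
    model_id: str = "rw_go_pav_split",
    mcmc: McmcConfig | None = None,
) -> FitResult:
    """Hierarchical fit of one go/no-go session per subject.

    Returns posterior draws for group means/sds and subject-level
    parameters, native-scale subject posterior means, and split-R-hat
    convergence diagnostics.
    """
    transforms = model_transforms(model_id)
    if len(sessions) < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    mcmc = mcmc or McmcConfig()
    ids, cues, choices, rewards = pack_gng_sessions(sessions)

    def loglik(native_free: np.ndarray) -> np.ndarray:
        full = expand_to_full(model_id, native_free)
        probs = trialwise_choice_probs(full, cues, choices, rewards)
        return np.log(np.maximum(probs, 1e-300)).sum(axis=1)

    def pointwise(native_free: np.ndarray) -> np.ndarray:
        full = expand_to_full(model_id, native_free)
        probs = trialwise_choice_probs(full, cues, choices, rewards)
        return np.log(np.maximum(probs, 1e-300)).ravel()

    return fit_hierarchical(
        loglik, transforms, len(sessions), mcmc,
        model_id=model_id, subject_ids=ids,
        data_hash=data_hash(sessions), pointwise_fn=pointwise,
    )


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted models by WAIC (deviance scale; lower is better)."""
    import arviz as az

    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("model comparison requires fits to identical data")
    rows = []
    for f in fits:
        if f.pointwise_loglik is None:
            raise ValueError(f"fit {f.model_id} has no pointwise log-likelihood")
        idata = az.from_dict(log_likelihood={"obs": f.pointwise_loglik})
        w = az.waic(idata, scale="deviance")
        rows.append({
            "model_id": f.model_id,
            "criterion": float(w["elpd_waic"]),
            "se": float(w["se"]),
        })
    table = pd.DataFrame(rows).sort_values(
        "criterion", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
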