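"""Default generating distributions for synthetic cohorts.

These are configuration, not ground truth: group means and standard
deviations live on the unconstrained sampling scale (probit scale for
unit-interval parameters, log scale for positive ones, raw scale
otherwise), centred on values typical of published fits of these tasks.
The native-scale implications of the location parameters: learning rate
~0.21, lapse ~0.05, sensitivities ~2.2, boundary separation ~1.5, starting
bias 0.5, non-decision time ~0.33 s.
"""

DEFAULTS_VERSION = "1"

#: go/no-go winning model, unconstrained-scale (mean, sd) per parameter
GNG_GROUP_DEFAULTS: dict[str, tuple[float, float]] = {
    "epsilon": (-0.8, 0.5),
    "b": (0.3, 0.6),
    "pi_approach": (0.4, 0.5),
    "pi_avoid": (0.4, 0.5),
    "rho_rew": (0.8, 0.4),
    "rho_pun": (0.8, 0.4),
    "xi": (-1.6, 0.4),
}

#: 4-parameter diffusion model, unconstrained-scale (mean, sd) per parameter
DDM_GROUP_DEFAULTS: dict[str, tuple[float, float]] = {
    "alpha": (0.4, 0.3),
    "beta": (0.0, 0.4),
    "delta": (0.4, 0.7),
    "tau": (-1.1, 0.25),
}

#: default cross-session correlation of subject-level parameters
DEFAULT_CROSS_SESSION_R = 0.7

#: drift magnitude used to simulate responses to the trained (unambiguous)
#: circle sizes; large enough for ~97% accuracy at default boundaries
TRAINED_DRIFT = 3.0

#: transform kind per generator parameter
GENERATOR_TRANSFORMS: dict[str, str] = {
    "epsilon": "probit", "xi": "probit",
    "b": "identity", "pi_approach": "identity", "pi_avoid": "identity",
    "rho_rew": "log", "rho_pun": "log",
    "alpha": "log", "beta": "probit", "delta": "identity", "tau": "log",
}
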