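"""Maps between unconstrained (sampling) and native parameter scales.

Hierarchical models place normal population distributions on an
unconstrained scale; each parameter declares how it maps to its native
range: identity for unbounded parameters, ``exp`` for positive ones, and
the inverse-probit (standard-normal CDF) for unit-interval ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ParamTransform:
    name: str
    kind: str  # {"identity", "log", "probit"}
    scale: float = 1.0  # multiplier applied after the probit map

    def to_native(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "identity":
            return z * 1.0
        if self.kind == "log":
            return np.exp(z)
        if self.kind == "probit":
            return stats.norm.cdf(z) * self.scale
        raise ValueError(self.kind)

    def to_unconstrained(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x * 1.0
        if self.kind == "log":
            return np.log(x)
        if self.kind == "probit":
            return stats.norm.ppf(x / self.scale)
        raise ValueError(self.kind)


def to_native_matrix(z: np.ndarray, transforms: list[ParamTransform]) -> np.ndarray:
    """Columnwise native-scale map of an (n, P) unconstrained matrix."""
    out = np.empty_like(np.asarray(z, dtype=float))
    for j, tr in enumerate(transforms):
        out[..., j] = tr.to_native(z[..., j])
    return out
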