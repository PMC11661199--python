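"""Two-stage test-retest reliability: Pearson and intraclass correlations.

Measures are paired across two sessions (k = 2).  The ICCs come from the
two-way mean squares of the subject x session layout (random subjects,
fixed sessions):

    ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)                 consistency
    ICC(A,1) = (MS_R - MS_E) /
               (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))             agreement

with F-based confidence intervals (Satterthwaite degrees of freedom for
agreement) following the McGraw & Wong single-measure procedures, and the
conventional band labels: < 0.4 poor, 0.4-0.75 moderate-good, > 0.75
excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PairedMeasures:
    """One measure observed for the same subjects in two sessions."""

    subjects: tuple
    session1: np.ndarray
    session2: np.ndarray

    def __post_init__(self):
        s1 = np.asarray(self.session1, dtype=float)
        s2 = np.asarray(self.session2, dtype=float)
        if s1.shape != s2.shape or s1.ndim != 1:
            raise ValueError("session vectors must be 1-D and equal length")
        if len(self.subjects) != s1.size:
            raise ValueError("subject ids do not match measure length")
        if np.any(~np.isfinite(s1)) or np.any(~np.isfinite(s2)):
            raise ValueError("paired measures must be complete (no NaN)")
        if s1.size < 3:
            raise ValueError("need at least 3 subjects")
        object.__setattr__(self, "session1", s1)
        object.__setattr__(self, "session2", s2)

    @property
    def n(self) -> int:
        return self.session1.size


@dataclass(frozen=True)
class ReliabilityEstimate:
    method: str  # {"pearson", "icc_a1", "icc_c1"}
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    undefined: bool = False

    @property
    def band(self) -> str:
        if not np.isfinite(self.coefficient):
            return "undefined"
        if self.coefficient < 0.4:
            return "poor"
        if self.coefficient <= 0.75:
            return "moderate-good"
        return "excellent"


@dataclass(frozen=True)
class AnovaDecomposition:
    """Two-way mean squares of the n x k subject-by-session layout."""

    ms_r: float  # between-subject
    ms_c: float  # between-session
    ms_e: float  # residual
    n: int
    k: int


def anova_decomposition(pm: PairedMeasures) -> AnovaDecomposition:
    x = np.column_stack([pm.session1, pm.session2])
    n, k = x.shape
    grand = x.mean()
    ss_r = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_c = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_t = np.sum((x - grand) ** 2)
    ss_e = max(ss_t - ss_r - ss_c, 0.0)
    return AnovaDecomposition(
        ms_r=ss_r / (n - 1), ms_c=ss_c / (k - 1),
        ms_e=ss_e / ((n - 1) * (k - 1)), n=n, k=k,
    )


def pearson(pm: PairedMeasures, ci_level: float = 0.95) -> ReliabilityEstimate:
    """Product-moment correlation with t-based p and Fisher-z CI."""
    if np.std(pm.session1) == 0 or np.std(pm.session2) == 0:
        return ReliabilityEstimate("pearson", np.nan, np.nan, np.nan, np.nan,
                                   undefined=True)
    r, p = stats.pearsonr(pm.session1, pm.session2)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(pm.n - 3)
    crit = stats.norm.ppf(0.5 + ci_level / 2)
    lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return ReliabilityEstimate("pearson", float(r), float(lo), float(hi),
                               float(p))


def icc(pm: PairedMeasures, flavor: str = "agreement",
        ci_level: float = 0.95) -> ReliabilityEstimate:
    """Single-measure two-way ICC: 'agreement' = ICC(A,1), 'consistency' = ICC(C,1)."""
    if flavor not in ("agreement", "consistency"):
        raise ValueError("flavor must be 'agreement' or 'consistency'")
    ms = anova_decomposition(pm)
    n, k = ms.n, ms.k
    msr, msc, mse = ms.ms_r, ms.ms_c, ms.ms_e
    total_var = np.var(np.concatenate([pm.session1, pm.session2]))
    if total_var == 0:
        return ReliabilityEstimate(
            "icc_a1" if flavor == "agreement" else "icc_c1",
            np.nan, np.nan, np.nan, np.nan, undefined=True)

    alpha = 1.0 - ci_level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    # significance test against 0 (psych/pingouin convention for both types)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = msr / mse if mse > 0 else np.inf
    p_value = float(stats.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0

    if flavor == "consistency":
        coef = (msr - mse) / (msr + (k - 1) * mse)
        if np.isfinite(f_obs):
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            lo = hi = coef
        return ReliabilityEstimate("icc_c1", float(coef), float(lo),
                                   float(hi), p_value)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    coef = (msr - mse) / denom if denom != 0 else np.nan
    # Satterthwaite df for the agreement interval
    if mse > 0 and 0 < coef < 1:
        a = (k * coef) / (n * (1 - coef))
        b = 1 + (k * coef * (n - 1)) / (n * (1 - coef))
        v = ((a * msc + b * mse) ** 2 /
             ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / df2))
        f_star = stats.f.ppf(1 - alpha / 2, df1, v)
        lo = (n * (msr - f_star * mse) /
              (f_star * (k * msc + (k * n - k - n) * mse) + n * msr))
        f_star2 = stats.f.ppf(1 - alpha / 2, v, df1)
        hi = (n * (f_star2 * msr - mse) /
              (k * msc + (k * n - k - n) * mse + n * f_star2 * msr))
    else:
        lo = hi = coef
    return ReliabilityEstimate("icc_a1", float(coef), float(lo), float(hi),
                               p_value)


def reliability_table(measures_s1: pd.DataFrame, measures_s2: pd.DataFrame,
                      measures: list[str] | None = None,
                      task: str | None = None,
                      tidy: bool = False) -> pd.DataFrame:
    """Reliability of every measure by all three methods.

    Inputs are per-session frames with a ``subject`` column plus one column
    per measure; subjects must match one-to-one across sessions.  Rows with
    a NaN measure in either session are dropped pairwise for that measure.
    Default output is wide (one row per measure, Table-1 shaped); with
    ``tidy=True`` one row per measure x method.
    """
    s1 = measures_s1.set_index("subject")
    s2 = measures_s2.set_index("subject")
    mismatch = set(s1.index).symmetric_difference(s2.index)
    if mismatch:
        raise ValueError(f"subjects not matched across sessions: {sorted(mismatch, key=str)}")
    if measures is None:
        measures = [c for c in s1.columns if c in s2.columns
                    and not c.startswith("n_") and c != "session"]
    rows = []
    for m in measures:
        pair = pd.DataFrame({"s1": s1[m], "s2": s2[m]}).dropna()
        pm = PairedMeasures(tuple(pair.index), pair["s1"].to_numpy(),
                            pair["s2"].to_numpy())
        est_p = pearson(pm)
        est_a = icc(pm, "agreement")
        est_c = icc(pm, "consistency")
        rows.append({
            "task": task, "measure": m, "n": pm.n,
            "pearson_r": est_p.coefficient, "pearson_p": est_p.p_value,
            "pearson_ci_low": est_p.ci_low, "pearson_ci_high": est_p.ci_high,
            "icc_a1": est_a.coefficient, "icc_a1_p": est_a.p_value,
            "icc_a1_ci_low": est_a.ci_low, "icc_a1_ci_high": est_a.ci_high,
            "icc_c1": est_c.coefficient, "icc_c1_p": est_c.p_value,
            "icc_c1_ci_low": est_c.ci_low, "icc_c1_ci_high": est_c.ci_high,
            "band": est_a.band,
        })
    wide = pd.DataFrame(rows)
    if not tidy:
        return wide
    out = []
    for _, row in wide.iterrows():
        for method, col in (("pearson", "pearson_r"), ("icc_a1", "icc_a1"),
                            ("icc_c1", "icc_c1")):
            pcol = "pearson_p" if method == "pearson" else f"{method}_p"
            coef = row[col]
            out.append({
                "task": row["task"], "measure": row["measure"],
                "method": method, "n": row["n"], "coefficient": coef,
                "ci_low": row[f"{method}_ci_low" if method != "pearson"
                              else "pearson_ci_low"],
                "ci_high": row[f"{method}_ci_high" if method != "pearson"
                               else "pearson_ci_high"],
                "p_value": row[pcol],
                "band": ("poor" if coef < 0.4 else
                         "moderate-good" if coef <= 0.75 else "excellent"),
            })
    return pd.DataFrame(out)
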