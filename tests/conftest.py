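"""Shared fixtures: simulated cohorts and hierarchical fits.

The expensive hierarchical fits are session-scoped so that module tests and
the acceptance suite share one MCMC run per (task, session).
"""

from __future__ import annotations

import numpy as np
import pytest

from affectbias.ddm_model import fit_hierarchical_ddm
from affectbias.gonogo_model import fit_hierarchical_gng
from affectbias.hierarchical import McmcConfig
from affectbias.synthetic_cohort import CohortConfig, simulate_cohort

GNG_COHORT_SEED = 11
AM_COHORT_SEED = 21
TRUE_CROSS_SESSION_R = 0.7


@pytest.fixture(scope="session")
def gng_cohort():
    """Default two-session go/no-go cohort (58 subjects, r_true = 0.7)."""
    return simulate_cohort(CohortConfig(
        task="gonogo", n_subjects=58, seed=GNG_COHORT_SEED,
        cross_session_r=TRUE_CROSS_SESSION_R))


@pytest.fixture(scope="session")
def am_cohort():
    """Default two-session ambiguous-midpoint cohort."""
    return simulate_cohort(CohortConfig(
        task="ambiguous_midpoint", n_subjects=58, seed=AM_COHORT_SEED,
        cross_session_r=TRUE_CROSS_SESSION_R))


@pytest.fixture(scope="session")
def gng_fits(gng_cohort):
    """Hierarchical winning-model fits of both go/no-go sessions."""
    mc = McmcConfig(chains=2, warmup=800, draws=1000, seed=1, thin_theta=2)
    return {
        s: fit_hierarchical_gng(
            gng_cohort.sessions(task="gonogo", session=s), mcmc=mc)
        for s in (1, 2)
    }


@pytest.fixture(scope="session")
def ddm_fit_s1(am_cohort):
    """Hierarchical 4-parameter diffusion fit of session 1."""
    return fit_hierarchical_ddm(
        am_cohort.sessions(task="ambiguous_midpoint", session=1),
        mcmc=McmcConfig(chains=2, warmup=500, draws=600, seed=5,
                        thin_theta=2))


def true_session_values(cohort, session: int):
    """Pivot the generating parameter table to subject x parameter."""
    col = f"session{session}"
    return cohort.true_params.pivot(
        index="subject", columns="parameter", values=col)


def recovery_correlation(cohort, fit, param: str, session: int = 1) -> float:
    true = true_session_values(cohort, session)
    est = fit.subject_means.set_index("subject").reindex(true.index)
    return float(np.corrcoef(true[param], est[param])[0, 1])
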