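"""Diffusion model: closed forms, first-passage density, sampler, fits."""

import numpy as np
import pytest
from scipy.integrate import quad

from affectbias.ddm_model import (
    DDMParams, EZMoments, choice_probability, ez_ddm, ez_per_session,
    sample_wiener, wiener_density, wiener_logdensity,
)
from affectbias.hierarchical import McmcConfig
from affectbias.synthetic_cohort import CohortConfig, simulate_cohort
from tests.conftest import recovery_correlation, true_session_values


class TestChoiceProbability:
    def test_zero_drift_returns_start_bias(self):
        assert choice_probability(DDMParams(2.0, 0.3, 0.0, 0.1)) == 0.3

    def test_closed_form_value(self):
        p = choice_probability(DDMParams(2.0, 0.5, 1.0, 0.0))
        expected = (1 - np.exp(-2)) / (1 - np.exp(-4))
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(0.8808, abs=1e-4)

    def test_start_near_boundary_is_almost_certain(self):
        assert choice_probability(DDMParams(2.0, 0.999, 0.5, 0.0)) > 0.99

    def test_continuous_at_zero_drift(self):
        lo = choice_probability(DDMParams(1.5, 0.4, -1e-9, 0.0))
        hi = choice_probability(DDMParams(1.5, 0.4, 1e-9, 0.0))
        assert lo == pytest.approx(0.4, abs=1e-6)
        assert hi == pytest.approx(0.4, abs=1e-6)

    def test_extreme_drift_is_finite(self):
        assert choice_probability(DDMParams(3.0, 0.5, 50.0, 0.0)) == \
            pytest.approx(1.0, abs=1e-12)
        assert choice_probability(DDMParams(3.0, 0.5, -50.0, 0.0)) == \
            pytest.approx(0.0, abs=1e-12)


PARAM_GRID = [
    DDMParams(1.5, 0.5, 1.0, 0.3),
    DDMParams(0.8, 0.3, -0.5, 0.2),
    DDMParams(2.5, 0.6, 0.0, 0.4),
    DDMParams(1.2, 0.7, 2.0, 0.25),
]


class TestWienerDensity:
    @pytest.mark.parametrize("p", PARAM_GRID)
    def test_density_integrates_to_choice_probability(self, p):
        for boundary in ("upper", "lower"):
            val, _ = quad(lambda t: float(wiener_density(t, boundary, p)),
                          p.tau, p.tau + 80, limit=500)
            target = choice_probability(p)
            if boundary == "lower":
                target = 1.0 - target
            assert val == pytest.approx(target, abs=1e-4)

    @pytest.mark.parametrize("p", PARAM_GRID)
    def test_reflection_identity(self, p):
        mirrored = DDMParams(p.alpha, 1.0 - p.beta, -p.delta, p.tau)
        t = np.linspace(p.tau + 0.01, p.tau + 3.0, 50)
        np.testing.assert_allclose(
            wiener_density(t, "upper", p),
            wiener_density(t, "lower", mirrored), rtol=1e-10)

    def test_density_nonnegative_and_zero_below_tau(self):
        p = DDMParams(1.5, 0.5, 1.0, 0.3)
        t = np.linspace(0.0, 5.0, 200)
        d = wiener_density(t, "upper", p)
        assert (d >= 0).all()
        assert (d[t <= p.tau] == 0).all()
        assert wiener_logdensity(0.2, "upper", p) == -np.inf

    def test_invalid_boundary_label_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            wiener_density(1.0, "top", PARAM_GRID[0])


class TestSampler:
    def test_symmetric_process_splits_evenly(self):
        p = DDMParams(1.5, 0.5, 0.0, 0.2)
        rt, upper = sample_wiener(p, 100_000, np.random.default_rng(0))
        assert abs(upper.mean() - 0.5) < 0.01
        assert rt.min() >= p.tau

    @pytest.mark.parametrize("p", PARAM_GRID[:2])
    def test_boundary_fraction_matches_closed_form(self, p):
        _, upper = sample_wiener(p, 200_000, np.random.default_rng(1))
        assert abs(upper.mean() - choice_probability(p)) < 0.005

    def test_rt_moments_match_quadrature(self):
        p = DDMParams(1.5, 0.5, 1.0, 0.3)
        rt, upper = sample_wiener(p, 200_000, np.random.default_rng(2))
        mean_quad, _ = quad(
            lambda t: t * float(wiener_density(t + p.tau, "upper", p)
                                + wiener_density(t + p.tau, "lower", p)),
            0, 60, limit=400)
        assert abs((rt.mean() - p.tau) - mean_quad) < 0.01


class TestEZ:
    def test_round_trip_single_point(self):
        p = DDMParams(1.5, 0.5, 1.0, 0.3)
        rt, upper = sample_wiener(p, 500_000, np.random.default_rng(3))
        m = EZMoments(pc=float(upper.mean()), vrt=float(np.var(rt, ddof=1)),
                      mrt=float(rt.mean()), n=rt.size)
        est = ez_ddm(m)
        assert est.v == pytest.approx(p.delta, abs=0.03)
        assert est.a == pytest.approx(p.alpha, abs=0.03)
        assert est.ter == pytest.approx(p.tau, abs=0.02)

    def test_mirrored_accuracy_flips_drift_sign_only(self):
        m = EZMoments(pc=0.8, vrt=0.09, mrt=0.6, n=100)
        mm = EZMoments(pc=0.2, vrt=0.09, mrt=0.6, n=100)
        a, b = ez_ddm(m), ez_ddm(mm)
        assert a.v == pytest.approx(-b.v)
        assert a.a == pytest.approx(b.a)
        assert a.ter == pytest.approx(b.ter)

    def test_scaling_convention(self):
        m = EZMoments(pc=0.75, vrt=0.12, mrt=0.55, n=80)
        s1, s01 = ez_ddm(m, s=1.0), ez_ddm(m, s=0.1)
        assert s01.v == pytest.approx(0.1 * s1.v)
        assert s01.a == pytest.approx(0.1 * s1.a)
        assert s01.ter == pytest.approx(s1.ter)

    def test_chance_accuracy_errors_without_correction(self):
        m = EZMoments(pc=0.5, vrt=0.1, mrt=0.5, n=40)
        with pytest.raises(ValueError, match="degenerate"):
            ez_ddm(m, edge_correction=False)
        est = ez_ddm(m, edge_correction=True)
        assert np.isfinite(est.v) and "edge_corrected" in est.flags

    def test_perfect_accuracy_edge_corrected(self):
        m = EZMoments(pc=1.0, vrt=0.05, mrt=0.45, n=40)
        est = ez_ddm(m)
        assert np.isfinite(est.v) and est.v > 0


class TestEZPerSession:
    def test_same_subject_twice_identical(self, am_cohort):
        sessions = am_cohort.sessions(task="ambiguous_midpoint", session=1)
        tbl = ez_per_session(sessions + sessions[:1])
        first = tbl[tbl["subject"] == sessions[0].subject_id]
        assert len(first) == 2
        assert first["v"].nunique() == 1

    def test_estimates_track_generating_drift(self, am_cohort):
        sessions = am_cohort.sessions(task="ambiguous_midpoint", session=1)
        tbl = ez_per_session(sessions).set_index("subject")
        true = true_session_values(am_cohort, 1)
        r = np.corrcoef(true["delta"], tbl.reindex(true.index)["v"])[0, 1]
        assert r > 0.5


class TestHierarchicalDDM:
    def test_posterior_beta_centred_when_generator_unbiased(self):
        cfg = CohortConfig(task="ambiguous_midpoint", n_subjects=20, seed=77,
                           group_mean={"beta": 0.0},
                           group_sd={"beta": 1e-6})
        cohort = simulate_cohort(cfg)
        from affectbias.ddm_model import fit_hierarchical_ddm
        fit = fit_hierarchical_ddm(
            cohort.sessions(task="ambiguous_midpoint", session=1),
            mcmc=McmcConfig(chains=2, warmup=300, draws=300, seed=3,
                            thin_theta=2))
        assert abs(fit.subject_means["beta"].mean() - 0.5) < 0.05

    def test_recovery_sanity(self, am_cohort, ddm_fit_s1):
        # acceptance suite holds the formal gates; here basic sanity
        assert len(ddm_fit_s1.subject_means) == 58
        assert (ddm_fit_s1.subject_means["alpha"] > 0).all()
        assert recovery_correlation(am_cohort, ddm_fit_s1, "tau") > 0.5
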