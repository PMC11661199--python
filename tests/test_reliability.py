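"""Pearson / ICC statistics against independent oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from affectbias.ddm_model import ez_per_session
from affectbias.reliability import (
    AnovaDecomposition, PairedMeasures, anova_decomposition, icc, pearson,
    reliability_table,
)
from affectbias.synthetic_cohort import CohortConfig, sample_paired_params, simulate_cohort


def _pm(x, y):
    return PairedMeasures(tuple(range(len(x))), np.asarray(x, float),
                          np.asarray(y, float))


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pearson(_pm(x, x)).coefficient == pytest.approx(1.0)
        assert pearson(_pm(x, -x + 5)).coefficient == pytest.approx(-1.0)

    def test_constant_vector_flagged_undefined(self):
        est = pearson(_pm([1, 1, 1, 1], [1, 2, 3, 4]))
        assert est.undefined and np.isnan(est.coefficient)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        a = pearson(_pm(x, y))
        b = pearson(_pm(3 * x + 2, 0.1 * y - 7))
        assert a.coefficient == pytest.approx(b.coefficient)

    def test_fisher_ci_close_to_bootstrap(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 58)
        y = 0.6 * x + rng.normal(0, 0.8, 58)
        est = pearson(_pm(x, y))
        idx = rng.integers(0, 58, size=(100_000, 58))
        bx, by = x[idx], y[idx]
        bx = bx - bx.mean(axis=1, keepdims=True)
        by = by - by.mean(axis=1, keepdims=True)
        rs = (bx * by).sum(1) / np.sqrt((bx**2).sum(1) * (by**2).sum(1))
        lo, hi = np.quantile(rs, [0.025, 0.975])
        assert est.ci_low == pytest.approx(lo, abs=0.02)
        assert est.ci_high == pytest.approx(hi, abs=0.02)


class TestICC:
    def test_perfect_agreement(self):
        pm = _pm([1, 2, 3], [1, 2, 3])
        assert icc(pm, "agreement").coefficient == pytest.approx(1.0)
        assert icc(pm, "consistency").coefficient == pytest.approx(1.0)

    def test_constant_shift_hand_anova(self):
        # x=(1,2,3), y=(2,3,4): MS_R=2, MS_C=1.5, MS_E=0
        pm = _pm([1, 2, 3], [2, 3, 4])
        ms = anova_decomposition(pm)
        assert (ms.ms_r, ms.ms_c, ms.ms_e) == (2.0, 1.5, 0.0)
        assert icc(pm, "consistency").coefficient == pytest.approx(1.0)
        assert icc(pm, "agreement").coefficient == pytest.approx(2.0 / 3.0)

    def test_matches_bruteforce_two_way_anova(self):
        # independent oracle: ICCs recomputed from scratch via the cell-mean
        # decomposition of the subject x session layout
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(0, 1, 10)
            y = rng.uniform(0.2, 0.9) * x + rng.normal(0, 1, 10) + \
                rng.normal(0, 0.5)
            X = np.column_stack([x, y])
            n, k = X.shape
            grand = X.mean()
            msr = k * ((X.mean(1) - grand) ** 2).sum() / (n - 1)
            msc = n * ((X.mean(0) - grand) ** 2).sum() / (k - 1)
            mse = (((X - X.mean(1, keepdims=True) - X.mean(0, keepdims=True)
                     + grand) ** 2).sum() / ((n - 1) * (k - 1)))
            icc_c = (msr - mse) / (msr + (k - 1) * mse)
            icc_a = (msr - mse) / (msr + (k - 1) * mse
                                   + k * (msc - mse) / n)
            pm = _pm(x, y)
            assert icc(pm, "consistency").coefficient == \
                pytest.approx(icc_c, abs=1e-10)
            assert icc(pm, "agreement").coefficient == \
                pytest.approx(icc_a, abs=1e-10)

    def test_matches_pingouin_reference(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(0, 1, 12)
            y = 0.5 * x + rng.normal(0, 0.9, 12) + 0.4
            long = pd.DataFrame({
                "subj": list(range(12)) * 2, "sess": [1] * 12 + [2] * 12,
                "y": np.concatenate([x, y])})
            ref = pg.intraclass_corr(long, targets="subj", raters="sess",
                                     ratings="y").set_index("Type")
            pm = _pm(x, y)
            a, c = icc(pm, "agreement"), icc(pm, "consistency")
            assert a.coefficient == pytest.approx(ref.loc["ICC(A,1)", "ICC"])
            assert c.coefficient == pytest.approx(ref.loc["ICC(C,1)", "ICC"])
            assert a.p_value == pytest.approx(ref.loc["ICC(A,1)", "pval"])
            # pingouin rounds its CI bounds to 2 decimals
            assert a.ci_low == pytest.approx(
                ref.loc["ICC(A,1)", "CI95"][0], abs=0.006)
            assert c.ci_high == pytest.approx(
                ref.loc["ICC(C,1)", "CI95"][1], abs=0.006)

    def test_shift_invariance_consistency_vs_agreement(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = 0.7 * x + rng.normal(0, 0.5, 20)
        base_c = icc(_pm(x, y), "consistency").coefficient
        base_a = icc(_pm(x, y), "agreement").coefficient
        shifted_c = icc(_pm(x, y + 2), "consistency").coefficient
        shifted_a = icc(_pm(x, y + 2), "agreement").coefficient
        assert shifted_c == pytest.approx(base_c)
        assert shifted_a < base_a

    def test_zero_variance_flagged(self):
        est = icc(_pm([1, 1, 1], [1, 1, 1]), "agreement")
        assert est.undefined

    def test_band_thresholds(self):
        ms = AnovaDecomposition(1, 1, 1, 10, 2)
        assert ms.n == 10  # container sanity
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        est = icc(_pm(x, x + rng.normal(0, 2.5, 40)), "agreement")
        assert est.band in ("poor", "moderate-good", "excellent")


class TestReliabilityTable:
    def _tables(self, n=20, n_measures=5, seed=0):
        rng = np.random.default_rng(seed)
        s1 = pd.DataFrame({"subject": range(n)})
        s2 = pd.DataFrame({"subject": range(n)})
        for i in range(n_measures):
            x = rng.normal(0, 1, n)
            s1[f"m{i}"] = x
            s2[f"m{i}"] = 0.6 * x + rng.normal(0, 0.8, n)
        return s1, s2

    def test_cardinality_wide_and_tidy(self):
        s1, s2 = self._tables()
        wide = reliability_table(s1, s2)
        tidy = reliability_table(s1, s2, tidy=True)
        assert len(wide) == 5
        assert len(tidy) == 15
        assert set(tidy["method"]) == {"pearson", "icc_a1", "icc_c1"}

    def test_duplicated_session_gives_unit_coefficients(self):
        s1, _ = self._tables()
        tab = reliability_table(s1, s1.copy())
        assert np.allclose(tab[["pearson_r", "icc_a1", "icc_c1"]], 1.0)

    def test_subject_mismatch_rejected(self):
        s1, s2 = self._tables()
        s2 = s2[s2["subject"] != 3]
        with pytest.raises(ValueError, match="3"):
            reliability_table(s1, s2)

    def test_noiseless_measures_recover_generating_correlation(self):
        cfg = CohortConfig(task="gonogo", n_subjects=2000, seed=6,
                           cross_session_r=0.7)
        tbl = sample_paired_params(cfg)
        grp = tbl[tbl["parameter"] == "b"]  # identity scale: measures as-is
        s1 = pd.DataFrame({"subject": grp["subject"], "b": grp["session1"]})
        s2 = pd.DataFrame({"subject": grp["subject"], "b": grp["session2"]})
        tab = reliability_table(s1, s2, measures=["b"])
        assert abs(tab.loc[0, "pearson_r"] - 0.7) < 0.05

    def test_noisy_estimates_attenuate_on_average(self):
        # two-stage reliability of EZ drift across replicate cohorts stays
        # below the generating correlation (measurement-noise attenuation)
        rs = []
        for seed in range(4):
            cohort = simulate_cohort(CohortConfig(
                task="ambiguous_midpoint", n_subjects=58, seed=300 + seed,
                cross_session_r=0.7))
            ez = {s: ez_per_session(
                cohort.sessions(task="ambiguous_midpoint", session=s))
                for s in (1, 2)}
            merged = ez[1].merge(ez[2], on="subject", suffixes=("_1", "_2"))
            rs.append(np.corrcoef(merged["v_1"], merged["v_2"])[0, 1])
        assert np.mean(rs) < 0.7
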