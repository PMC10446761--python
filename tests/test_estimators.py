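"""Univariable estimator tests: Wald, IVW, Egger, Q, PRESSO-style outliers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm

from lipidmr.estimators import (cochran_q, detect_outliers, egger, ivw,
                                significance_label, wald_ratio)
from lipidmr.harmonize import HarmonizedRecord
from lipidmr.simulate import CausalModel, simulate_sumstats
from lipidmr.harmonize import harmonize

from conftest import make_hset


def rec(beta_X=0.1, beta_Y=0.02, se_Y=0.1, se_X=0.01):
    return HarmonizedRecord(rsid="rs1", beta_X=beta_X, se_X=se_X,
                            beta_Y=beta_Y, se_Y=se_Y, aligned_allele="A")


class TestWaldRatio:
    @pytest.mark.parametrize("bx, by, sy, beta, se", [
        (0.1, 0.02, 0.1, 0.2, 1.0),
        (0.1, 0.0, 0.1, 0.0, 1.0),
        (-0.1, 0.02, 0.1, -0.2, 1.0),
    ])
    def test_arithmetic(self, bx, by, sy, beta, se):
        est = wald_ratio(rec(beta_X=bx, beta_Y=by, se_Y=sy))
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(rec(beta_X=0.0))


class TestIVW:
    def test_exact_proportionality(self, proportional_hset):
        est = ivw(proportional_hset, mode="auto")
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-12)
        assert est.method == "ivw_fe"  # Q p = 1 so the auto rule picks FE

    def test_single_record_reduces_to_wald(self):
        h = make_hset([0.1], [0.02], [0.1])
        est = ivw(h)
        wald = wald_ratio(h.records[0])
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.1, 30)
        y = 0.15 * x + rng.normal(0, 0.02, 30)
        sy = rng.uniform(0.01, 0.05, 30)
        h = make_hset(x, y, sy)
        est = ivw(h, mode="fe")
        fit = sm.WLS(y, x, weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
        # FE standard error is the normal-equations SE without residual scaling
        se_fe = float(np.sqrt(1 / np.sum(x**2 / sy**2)))
        assert est.se == pytest.approx(se_fe, rel=1e-12)

    def test_recovers_planted_effect(self):
        model = CausalModel(m_variants=50, theta=0.2, seed=21,
                            n_exposure=300_000, n_outcome=300_000)
        study = simulate_sumstats(model)
        h = harmonize(study.exposure, study.outcome)
        est = ivw(h, mode="auto")
        assert abs(est.beta - 0.2) < 2 * est.se

    def test_random_effects_never_shrinks_se(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            k = int(rng.integers(3, 30))
            h = make_hset(rng.normal(0, 0.1, k),
                          rng.normal(0, 0.05, k),
                          rng.uniform(0.01, 0.1, k))
            fe, re = ivw(h, "fe"), ivw(h, "re")
            assert re.se >= fe.se
            q, q_df, _ = cochran_q(h, fe.beta)
            if q <= q_df:
                assert re.se == pytest.approx(fe.se)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_joint_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        k = 8
        x = rng.normal(0, 0.1, k)
        y = rng.normal(0, 0.05, k)
        sy = rng.uniform(0.01, 0.1, k)
        flip = rng.choice([-1.0, 1.0], k)
        a = ivw(make_hset(x, y, sy), "fe")
        b = ivw(make_hset(x * flip, y * flip, sy), "fe")
        assert b.beta == pytest.approx(a.beta, rel=1e-10)
        assert b.se == pytest.approx(a.se, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_hset([0.0, 0.0], [0.1, 0.2], [0.1, 0.1]))
        with pytest.raises(ValueError):
            ivw(make_hset([0.1, 0.2], [0.1, 0.2], [0.1, 0.1]), mode="bogus")


class TestCochranQ:
    def test_zero_heterogeneity(self, proportional_hset):
        q, df, p = cochran_q(proportional_hset, 0.2)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_discordant_ratio_positive_q(self):
        h = make_hset([0.1, 0.1], [0.02, 0.2], [0.05, 0.05])
        est = ivw(h, "fe")
        q, _, _ = cochran_q(h, est.beta)
        assert q > 0

    def test_detects_balanced_pleiotropy(self):
        # pleiotropy inflates Q: the test should reject in most replicates
        hits = 0
        n_rep = 60
        for i in range(n_rep):
            model = CausalModel(m_variants=40, theta=0.1, pleiotropy_sd=0.02,
                                seed=1000 + i)
            study = simulate_sumstats(model)
            h = harmonize(study.exposure, study.outcome)
            est = ivw(h, "fe")
            _, _, p = cochran_q(h, est.beta)
            hits += p < 0.05
        assert hits > n_rep / 2


class TestEgger:
    def test_exact_affine_fixture(self, linear_hset):
        est = egger(linear_hset)
        assert est.egger_intercept == pytest.approx(0.05, abs=1e-12)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-10)

    def test_zero_intercept_fixture_matches_ivw(self, proportional_hset):
        eg = egger(proportional_hset)
        fe = ivw(proportional_hset, "fe")
        assert eg.beta == pytest.approx(fe.beta, abs=1e-10)
        assert eg.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_oracle_with_orientation(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 0.1, 25)
        y = 0.03 + 0.2 * x + rng.normal(0, 0.02, 25)
        sy = rng.uniform(0.02, 0.06, 25)
        h = make_hset(x, y, sy)
        est = egger(h)
        sgn = np.sign(x)
        X = sm.add_constant(np.abs(x))
        fit = sm.WLS(y * sgn, X, weights=1 / sy**2).fit()
        assert est.egger_intercept == pytest.approx(fit.params[0], rel=1e-8)
        assert est.beta == pytest.approx(fit.params[1], rel=1e-8)

    def test_orientation_does_not_mutate_input(self):
        h = make_hset([-0.1, 0.2, -0.3], [0.02, 0.04, 0.06], 0.1)
        before = h.df.copy()
        egger(h)
        assert h.df.equals(before)

    def test_recovers_directional_pleiotropy(self):
        # mean intercept over replicates approaches the mean direct effect
        intercepts = []
        for i in range(60):
            model = CausalModel(m_variants=50, theta=0.1,
                                pleiotropy_mean=0.005, pleiotropy_sd=0.002,
                                seed=2000 + i)
            study = simulate_sumstats(model)
            h = harmonize(study.exposure, study.outcome)
            intercepts.append(egger(h).egger_intercept)
        # sign mis-orientation at weakly associated variants attenuates the
        # intercept slightly; allow ~20% slack around the planted 0.005
        assert np.mean(intercepts) == pytest.approx(0.005, abs=1e-3)
        assert np.mean(intercepts) > 3 * np.std(intercepts) / np.sqrt(60)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger(make_hset([0.1, 0.2], [0.02, 0.04], 0.1))


class TestDetectOutliers:
    def make_study(self, seed, outlier=False):
        model = CausalModel(m_variants=20, theta=0.2, seed=seed,
                            n_exposure=300_000, n_outcome=300_000)
        study = simulate_sumstats(model)
        h = harmonize(study.exposure, study.outcome)
        if outlier:
            # plant one variant with a direct effect 10x its outcome SE
            df = h.df.copy()
            df.loc[0, "beta_Y"] += 10 * df.loc[0, "se_Y"]
            h.df = df
        return h

    def test_deterministic_under_seed(self):
        h = self.make_study(3)
        a = detect_outliers(h, n_sim=1000, seed=42)
        b = detect_outliers(h, n_sim=1000, seed=42)
        assert a.global_p == b.global_p
        assert a.outliers == b.outliers
        assert a.outlier_p == b.outlier_p

    def test_null_data_not_flagged(self):
        h = self.make_study(4)
        res = detect_outliers(h, n_sim=1000, seed=0)
        assert res.global_p > 0.05
        assert res.outliers == []

    def test_planted_outlier_flagged_and_corrected(self):
        h = self.make_study(5, outlier=True)
        res = detect_outliers(h, n_sim=2000, seed=0)
        assert res.global_p < 0.05
        assert h.df.rsid[0] in res.outliers
        corrected = res.estimate_corrected
        assert corrected is not None
        assert abs(corrected.beta - 0.2) < 3 * corrected.se

    def test_small_sets_rejected(self):
        h = make_hset([0.1, 0.2, 0.3], [0.02, 0.04, 0.06], 0.1)
        with pytest.raises(ValueError, match="4 instruments"):
            detect_outliers(h)
        with pytest.raises(ValueError, match="n_sim"):
            detect_outliers(self.make_study(6), n_sim=10)


class TestSignificanceLabel:
    @pytest.mark.parametrize("p, x, y, expected", [
        (0.004, 6, 2, "strong"),       # threshold 0.05/12 = 0.0041667
        (0.03, 6, 2, "suggestive"),
        (0.05, 6, 2, "null"),          # strict upper bound
        (0.0042, 6, 2, "suggestive"),
        (1e-6, 1, 1, "strong"),
    ])
    def test_rule(self, p, x, y, expected):
        assert significance_label(p, x, y) == expected

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            significance_label(0.01, 0, 1)
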