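"""Comparator PRS methods: unadjusted, P+T, LDpred-inf, So, Mak."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ebprs import DataError
from ebprs.comparators import (
    LDpredInfConfig,
    LindseyConfig,
    PTConfig,
    clump,
    ldpred_inf_weights,
    mak_weights,
    pt_tune,
    pt_weights,
    so_weights,
    standardized_scale_factors,
    tweedie_posterior_mean,
    unadjusted_weights,
)
from ebprs.effect_model import EffectSizeModel, sample_z

from conftest import make_genotypes, sumstats_frame


class TestUnadjusted:
    def test_identity_weights(self, small_sumstats):
        w = unadjusted_weights(small_sumstats)
        np.testing.assert_array_equal(w["weight"], small_sumstats["beta_hat"])


def greedy_clump_oracle(p, snp_ids, corr, r2_threshold):
    """Brute-force re-execution of the greedy clumping trace."""
    remaining = sorted(range(len(p)), key=lambda i: (p[i], snp_ids[i]))
    retained = []
    while remaining:
        lead = remaining.pop(0)
        retained.append(snp_ids[lead])
        remaining = [j for j in remaining
                     if corr[lead, j] ** 2 <= r2_threshold]
    return retained


class TestClump:
    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(0)
        g = make_genotypes(rng.integers(0, 3, (200, 4)).astype(np.int8))
        ss = sumstats_frame(z=[1.0, 2.0, 0.5, 3.0])
        kept = clump(ss, g, PTConfig(r2_threshold=0.1))
        assert sorted(kept) == sorted(ss["snp_id"])

    def test_duplicated_column_keeps_smaller_p(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, (100, 1)).astype(np.int8)
        g = make_genotypes(np.hstack([col, col]))
        ss = sumstats_frame(z=[5.7, 3.9])  # p = 1e-8-ish, 1e-4-ish
        assert ss.loc[0, "p"] < ss.loc[1, "p"]
        kept = clump(ss, g, PTConfig())
        assert kept == ["snp0"]

    def test_matches_greedy_trace_oracle(self):
        # 5 SNPs with a controlled block-correlation structure
        rng = np.random.default_rng(7)
        base = rng.normal(size=(400, 2))
        latent = np.column_stack([
            base[:, 0], 0.9 * base[:, 0] + 0.44 * rng.normal(size=400),
            base[:, 1], 0.8 * base[:, 1] + 0.6 * rng.normal(size=400),
            rng.normal(size=400),
        ])
        dos = (latent > np.quantile(latent, 0.4, axis=0)).astype(np.int8) + \
              (latent > np.quantile(latent, 0.8, axis=0)).astype(np.int8)
        g = make_genotypes(dos)
        ss = sumstats_frame(z=[4.0, 4.5, 2.0, 2.5, 1.0])
        x = dos.astype(float)
        corr = np.corrcoef(x, rowvar=False)
        for thr in (0.1, 0.5):
            kept = clump(ss, g, PTConfig(r2_threshold=thr))
            oracle = greedy_clump_oracle(ss["p"].to_numpy(), list(ss["snp_id"]),
                                         corr, thr)
            assert kept == oracle

    def test_missing_genotypes_treated_uncorrelated(self):
        g = make_genotypes(np.array([[0, 1], [2, 1], [1, 0]], dtype=np.int8),
                           snp_ids=["snp0", "snp1"])
        ss = sumstats_frame(z=[1.0, 2.0, 3.0])  # snp2 has no genotypes
        kept = clump(ss, g, PTConfig())
        assert "snp2" in kept


class TestPTWeights:
    def test_cutoff_filtering_counts(self):
        ss = sumstats_frame(beta_hat=[0.1] * 6)
        ss["p"] = [1e-6, 1e-3, 0.02, 0.2, 0.6, 0.9]
        retained = list(ss["snp_id"])
        w = pt_weights(ss, retained, 5e-2)
        assert int((w["weight"] != 0).sum()) == 3
        w_all = pt_weights(ss, retained, 1.0)
        np.testing.assert_array_equal(w_all["weight"], ss["beta_hat"])
        w_none = pt_weights(ss, retained, 1e-9)
        assert not w_none["weight"].to_numpy().any()

    def test_tune_tie_breaks_to_larger_cutoff(self, small_study, small_sumstats):
        _, test, _ = small_study
        # grid of one -> that cutoff
        best, _, _ = pt_tune(small_sumstats, test, PTConfig(p_grid=(0.05,)))
        assert best == 0.05
        # two cutoffs spanning all SNPs give identical weights -> larger wins
        pmax = small_sumstats["p"].max()
        best, _, table = pt_tune(
            small_sumstats, test,
            PTConfig(p_grid=(1.0, (pmax + 1) / 2 if pmax < 1 else 1.0)))
        assert best == 1.0

    def test_tune_finds_strong_snps(self):
        # only a handful of very strong causal SNPs: stringent cutoffs win
        import ebprs
        hits = 0
        for seed in range(6):
            cfg = ebprs.SimConfig(m=300, causal_prop=10 / 300,
                                  effect_var_scale=0.02,
                                  n0_train=800, n1_train=800,
                                  n0_test=150, n1_test=150, seed=seed)
            tr, te, _ = ebprs.simulate_case_control(cfg)
            ss = ebprs.compute_sumstats(tr)
            best, _, _ = pt_tune(ss, te)
            hits += best <= 5e-2
        assert hits >= 4

    def test_tune_requires_phenotypes(self, small_sumstats):
        g = make_genotypes([[0], [1]], snp_ids=["snp1"])
        with pytest.raises(DataError, match="phenotypes"):
            pt_tune(small_sumstats, g)


class TestLDpredInf:
    def test_identity_ld_closed_form(self):
        ss = sumstats_frame(z=[1.0, -2.0, 0.5, 3.0])
        n, h2, m = 2000.0, 0.5, 4
        w = ldpred_inf_weights(ss, LDpredInfConfig(h2=h2, n=n))
        expected = (ss["z"] / np.sqrt(n)) * (n * h2) / (n * h2 + m)
        np.testing.assert_allclose(w["weight"], expected, atol=1e-10)

    def test_vanishing_ridge_limit(self):
        ss = sumstats_frame(z=[1.0, -2.0])
        rng = np.random.default_rng(3)
        a = rng.standard_normal((60, 2))
        d = np.corrcoef(a, rowvar=False)
        w = ldpred_inf_weights(ss, LDpredInfConfig(h2=1e9, n=1000, ld_matrix=d))
        expected = np.linalg.inv(d) @ (ss["z"].to_numpy() / np.sqrt(1000))
        np.testing.assert_allclose(w["weight"], expected, atol=1e-8)

    def test_dense_solve_matches_explicit_inverse(self):
        rng = np.random.default_rng(4)
        m = 4
        a = rng.standard_normal((80, m))
        d = np.corrcoef(a, rowvar=False)
        ss = sumstats_frame(z=list(rng.standard_normal(m)))
        n, h2 = 1500.0, 0.3
        w = ldpred_inf_weights(ss, LDpredInfConfig(h2=h2, n=n, ld_matrix=d))
        lam = m / (n * h2)
        expected = np.linalg.inv(lam * np.eye(m) + d) @ (
            ss["z"].to_numpy() / np.sqrt(n))
        np.testing.assert_allclose(w["weight"], expected, atol=1e-10)

    def test_scale_factors_ignore_constant_columns(self):
        g = make_genotypes([[1, 0], [1, 2], [1, 1]])
        s = standardized_scale_factors(g)
        assert s[0] == 0.0
        assert s[1] > 0


class TestSoMethod:
    def test_tweedie_matches_mixture_posterior_mean(self):
        # closed-form oracle from the parametric model on mixture-simulated z;
        # the nonparametric estimate is accurate where data are dense and its
        # error grows in the sparse |z|~3-4 transition region, so the check is
        # uniform on the dense range and root-mean-square on [-4, 4]
        ne = 2000.0
        model = EffectSizeModel(k=1, pi=np.array([0.8, 0.2]),
                                sigma2=np.array([3.0 / ne]), ne=ne)
        z = sample_z(model, 60_000, seed=21)
        mu_np = tweedie_posterior_mean(z)
        v = model.v[0]
        post = (0.2 * stats.norm.pdf(z, 0, np.sqrt(v))) / (
            0.8 * stats.norm.pdf(z) + 0.2 * stats.norm.pdf(z, 0, np.sqrt(v)))
        mu_closed = post * (1 - 1 / v) * z
        err = np.abs(mu_np - mu_closed)
        assert err[np.abs(z) <= 2.5].max() < 0.15
        sel = np.abs(z) <= 4
        assert np.sqrt((err[sel] ** 2).mean()) < 0.10

    def test_null_ltdr_gives_zero_weight(self, small_sumstats):
        null = EffectSizeModel(k=1, pi=np.array([1.0, 0.0]),
                               sigma2=np.array([1e-3]), ne=2000.0)
        w = so_weights(small_sumstats, kappa=0.01, model=null)
        np.testing.assert_allclose(w["weight"], 0.0, atol=1e-200)

    def test_invalid_prevalence(self, small_sumstats):
        with pytest.raises(DataError):
            so_weights(small_sumstats, kappa=1.5)

    def test_weights_finite(self, small_sumstats, two_component_model):
        model = EffectSizeModel(k=2, pi=np.array([0.9, 0.07, 0.03]),
                                sigma2=np.array([0.002, 0.01]), ne=2000.0)
        w = so_weights(small_sumstats, kappa=0.01, model=model)
        assert np.isfinite(w["weight"]).all()


class TestMakMethod:
    def test_ltdr_limits(self, small_sumstats):
        ne = 2000.0
        saturated = EffectSizeModel(k=1, pi=np.array([0.0, 1.0]),
                                    sigma2=np.array([2.0 / ne]), ne=ne)
        w = mak_weights(small_sumstats, saturated)
        np.testing.assert_allclose(w["weight"], small_sumstats["beta_hat"],
                                   rtol=1e-10)
        null = EffectSizeModel(k=1, pi=np.array([1.0, 0.0]),
                               sigma2=np.array([2.0 / ne]), ne=ne)
        w0 = mak_weights(small_sumstats, null)
        np.testing.assert_allclose(w0["weight"], 0.0, atol=1e-200)

    def test_shrinkage_bound(self, small_sumstats):
        model = EffectSizeModel(k=2, pi=np.array([0.85, 0.1, 0.05]),
                                sigma2=np.array([0.001, 0.005]), ne=2000.0)
        w = mak_weights(small_sumstats, model)
        assert (np.abs(w["weight"]) <=
                np.abs(small_sumstats["beta_hat"]) + 1e-15).all()
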