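"""Spike-and-slab mixture: density, ltdr, posterior means, EM, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from ebprs import DataError
from ebprs.effect_model import (
    EffectSizeModel,
    em_fit,
    ltdr,
    marginal_density,
    posterior_mean_effect,
    sample_z,
    select_alpha,
)

from conftest import sumstats_frame


def pure_null_model(ne=1000.0):
    return EffectSizeModel(k=1, pi=np.array([1.0, 0.0]),
                           sigma2=np.array([3.0 / ne]), ne=ne)


def quadrature_posterior_mean(z, model, se=1.0):
    """Independent oracle: E(beta|z) = se * E(mu|z) by adaptive quadrature
    over the continuous mixture posterior (the null point mass contributes
    only to the denominator)."""
    tau2 = model.ne * model.sigma2
    num = den = 0.0
    for pi_j, t2 in zip(model.pi[1:], tau2):
        if pi_j == 0:
            continue
        sd = np.sqrt(t2)
        num += pi_j * quad(
            lambda mu: mu * stats.norm.pdf(z - mu) * stats.norm.pdf(mu, 0, sd),
            -40 * sd, 40 * sd, limit=400)[0]
        den += pi_j * quad(
            lambda mu: stats.norm.pdf(z - mu) * stats.norm.pdf(mu, 0, sd),
            -40 * sd, 40 * sd, limit=400)[0]
    den += model.pi[0] * stats.norm.pdf(z)
    return se * num / den


class TestMarginalDensity:
    def test_pure_null_is_standard_normal(self):
        m = pure_null_model()
        zs = np.linspace(-4, 4, 9)
        np.testing.assert_allclose(marginal_density(zs, m),
                                   stats.norm.pdf(zs), rtol=1e-12)

    def test_known_two_component_value(self):
        # 0.9*phi(0) + 0.1*phi(0; 0, 4) = 0.9*0.39894 + 0.1*0.19947
        ne = 1000.0
        m = EffectSizeModel(k=1, pi=np.array([0.9, 0.1]),
                            sigma2=np.array([3.0 / ne]), ne=ne)
        assert marginal_density(0.0, m) == pytest.approx(0.37900, abs=5e-6)

    def test_normalization(self):
        ne = 1000.0
        m = EffectSizeModel(k=1, pi=np.array([0.9, 0.1]),
                            sigma2=np.array([3.0 / ne]), ne=ne)
        total = quad(lambda z: marginal_density(z, m), -12, 12, limit=400)[0]
        assert total == pytest.approx(1.0, abs=1e-6)


class TestLtdr:
    def test_null_and_saturated_limits(self, two_component_model):
        zs = np.linspace(-3, 3, 7)
        null = pure_null_model()
        np.testing.assert_allclose(ltdr(zs, null).sum(axis=1), 0.0, atol=1e-300)
        m = EffectSizeModel(k=2, pi=np.array([0.0, 0.6, 0.4]),
                            sigma2=np.array([0.002, 0.01]), ne=1000.0)
        np.testing.assert_allclose(ltdr(zs, m).sum(axis=1), 1.0, rtol=1e-12)

    def test_direct_bayes_value(self):
        ne = 1000.0
        m = EffectSizeModel(k=1, pi=np.array([0.9, 0.1]),
                            sigma2=np.array([3.0 / ne]), ne=ne)
        expected = (0.1 * stats.norm.pdf(3, 0, 2)) / (
            0.9 * stats.norm.pdf(3) + 0.1 * stats.norm.pdf(3, 0, 2))
        assert ltdr(np.array([3.0]), m)[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_rows_bounded_by_one(self, two_component_model):
        zs = np.linspace(-8, 8, 33)
        r = ltdr(zs, two_component_model)
        assert (r >= 0).all()
        assert (r.sum(axis=1) <= 1 + 1e-12).all()


class TestPosteriorMean:
    def test_pure_null_gives_zero_weights(self):
        ss = sumstats_frame(z=[0.5, -2.0, 4.0])
        eff = posterior_mean_effect(ss, pure_null_model())
        np.testing.assert_allclose(eff.beta_tilde, 0.0, atol=1e-200)

    def test_known_shrinkage_factor(self):
        # pi0=0, K=1, ne*sigma1^2=1 -> beta_tilde = beta_hat / 2
        ne = 1000.0
        m = EffectSizeModel(k=1, pi=np.array([0.0, 1.0]),
                            sigma2=np.array([1.0 / ne]), ne=ne)
        ss = sumstats_frame(beta_hat=[0.4, -0.2])
        eff = posterior_mean_effect(ss, m)
        np.testing.assert_allclose(eff.beta_tilde, [0.2, -0.1], rtol=1e-12)

    def test_matches_quadrature_oracle(self, two_component_model):
        se = 0.05
        zs = np.linspace(-6, 6, 25)
        ss = sumstats_frame(z=list(zs), se=[se] * zs.size)
        eff = posterior_mean_effect(ss, two_component_model)
        oracle = [quadrature_posterior_mean(z, two_component_model, se)
                  for z in zs]
        np.testing.assert_allclose(eff.beta_tilde, oracle, atol=1e-6)

    def test_shrinkage_never_inflates_and_preserves_sign(self, two_component_model):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 2, size=500)
        ss = sumstats_frame(z=list(z))
        eff = posterior_mean_effect(ss, two_component_model)
        beta_hat = ss["beta_hat"].to_numpy()
        assert (np.abs(eff.beta_tilde) <= np.abs(beta_hat) + 1e-15).all()
        nz = eff.beta_tilde != 0
        assert (np.sign(eff.beta_tilde[nz]) == np.sign(beta_hat[nz])).all()

    def test_no_shrinkage_limit(self):
        # strong signal components, no null mass -> beta_tilde ~ beta_hat
        ne = 1000.0
        m = EffectSizeModel(k=1, pi=np.array([0.0, 1.0]),
                            sigma2=np.array([1e8 / ne]), ne=ne)
        ss = sumstats_frame(z=[1.0, -3.0])
        eff = posterior_mean_effect(ss, m)
        np.testing.assert_allclose(eff.beta_tilde, ss["beta_hat"], rtol=1e-6)


class TestEMFit:
    def test_defaults(self, small_sumstats):
        from ebprs.effect_model import train
        model, _ = train(small_sumstats)
        assert model.k == 3
        assert model.alpha == pytest.approx(len(small_sumstats) / 20.0)

    def test_monotone_loglik_and_ordered_components(self):
        rng = np.random.default_rng(11)
        z = np.r_[rng.standard_normal(4000), rng.normal(0, 2.0, 600)]
        model = em_fit(z, ne=2000.0, k=3)
        path = model.loglik_path
        scale = np.maximum(1.0, np.abs(path[:-1]))
        assert (np.diff(path) >= -1e-9 * scale).all()
        assert (np.diff(model.sigma2) > 0).all() or model.k == 1
        assert abs(model.pi.sum() - 1) < 1e-10

    def test_parameter_recovery(self):
        true = EffectSizeModel(k=1, pi=np.array([0.9, 0.1]),
                               sigma2=np.array([2.0 / 2000.0]), ne=2000.0)
        z = sample_z(true, 50_000, seed=123)
        # recovery is a maximum-likelihood property: no null pseudo-count,
        # tight convergence (the MAP pseudo-count intentionally biases pi0 up)
        fit = em_fit(z, ne=2000.0, k=1, alpha=0.0, tol=1e-9)
        assert fit.pi[0] == pytest.approx(0.9, abs=0.02)
        assert fit.sigma2[0] == pytest.approx(2.0 / 2000.0, rel=0.10)

    def test_scale_invariance_in_ne(self):
        # same z fitted at ne and 4*ne: v identical, sigma2 scales by 1/4
        true = EffectSizeModel(k=1, pi=np.array([0.9, 0.1]),
                               sigma2=np.array([2.0 / 2000.0]), ne=2000.0)
        z = sample_z(true, 20_000, seed=5)
        f1 = em_fit(z, ne=2000.0, k=2)
        f4 = em_fit(z, ne=8000.0, k=2)
        np.testing.assert_allclose(f1.v, f4.v, rtol=1e-12)
        np.testing.assert_allclose(f1.sigma2 / f4.sigma2, 4.0, rtol=1e-10)

    def test_input_validation(self):
        with pytest.raises(DataError):
            em_fit(np.array([]), ne=100.0)
        with pytest.raises(DataError):
            em_fit(np.array([1.0, np.nan]), ne=100.0)
        with pytest.raises(DataError):
            em_fit(np.ones(10), ne=100.0, k=0)


class TestSampleZ:
    def test_determinism_and_total_variance(self):
        m = EffectSizeModel(k=1, pi=np.array([0.9, 0.1]),
                            sigma2=np.array([2.0 / 1000.0]), ne=1000.0)
        z1 = sample_z(m, 100_000, seed=9)
        z2 = sample_z(m, 100_000, seed=9)
        np.testing.assert_array_equal(z1, z2)
        # law of total variance: 0.9*1 + 0.1*3 = 1.2
        assert z1.var() == pytest.approx(1.2, abs=3 * np.sqrt(2 / 1e5) * 1.2 + 0.02)
        null = pure_null_model()
        assert sample_z(null, 50_000, seed=1).var() == pytest.approx(
            1.0, abs=3 * np.sqrt(2 / 5e4))


class TestSelectAlpha:
    def test_single_grid_value_and_determinism(self):
        true = EffectSizeModel(k=1, pi=np.array([0.9, 0.1]),
                               sigma2=np.array([2.0 / 1000.0]), ne=1000.0)
        z = sample_z(true, 2000, seed=2)
        a, _ = select_alpha(z, ne=1000.0, k=1, alpha_grid=[37.0], n_boot=2, seed=0)
        assert a == 37.0
        a1, _ = select_alpha(z, ne=1000.0, k=1,
                             alpha_grid=[20.0, 100.0], n_boot=3, seed=4)
        a2, _ = select_alpha(z, ne=1000.0, k=1,
                             alpha_grid=[20.0, 100.0], n_boot=3, seed=4)
        assert a1 == a2

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            select_alpha(np.ones(100), ne=100.0, alpha_grid=[], n_boot=5)
        with pytest.raises(DataError):
            select_alpha(np.ones(100), ne=100.0, alpha_grid=[1.0], n_boot=1)


class TestSerialization:
    def test_model_file_roundtrip(self, tmp_path, two_component_model):
        path = tmp_path / "model.tsv"
        two_component_model.loglik = -123.456
        two_component_model.to_file(path)
        back = EffectSizeModel.from_file(path)
        np.testing.assert_array_equal(back.pi, two_component_model.pi)
        np.testing.assert_array_equal(back.sigma2, two_component_model.sigma2)
        assert back.ne == two_component_model.ne
        assert back.loglik == two_component_model.loglik
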