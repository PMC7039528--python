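"""Synthetic case-control data generators.

Two designs are provided:

1. Independent-SNP design: per-SNP reference-allele frequencies are drawn
   from a uniform or scaled-Beta distribution on (0.05, 0.95); standardized
   effects follow the point-normal ``mu ~ (1-p) delta_0 + p N(0, c*Ne)``
   (defaults p = 0.1, c = 0.001); control genotypes are Bin(2, f0) and case
   genotypes Bin(2, f1) with f1 implied by the log-OR, sampled
   retrospectively (genotype given status) under a low-prevalence
   approximation f0 ~= population frequency. Optional train/test divergence
   perturbs test frequencies and/or effect sizes.

2. Phenotypes on existing genotypes: a sparse set of causal SNPs with
   log-ORs ~ N(0, beta_var) enters a logistic model whose intercept is
   solved by bisection to hit a target case fraction.

A Gaussian-copula block sampler provides synthetic correlated genotypes for
exercising LD-aware steps (clumping, LDpred-inf) without real panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import stats
from scipy.special import expit

from ._exceptions import DataError
from .sumstats import (
    GenotypeData,
    compute_sumstats,
    effective_sample_size,
    write_genotypes,
    write_phenotypes,
    write_sumstats,
)

_FREQ_LO, _FREQ_HI = 0.05, 0.95
_ROW_CHUNK = 512  # genotype sampling block, bounds peak memory


@dataclass
class Divergence:
    """Train/test population divergence options."""

    test_freq_dist: str | None = None          # e.g. "scaled-beta"
    test_freq_params: tuple = (0.8, 0.8)
    effect_shift_var_scale: float | None = None  # c' in N(0, c'*Ne) on mu scale


@dataclass
class SimConfig:
    """Independent-SNP study design. Defaults reproduce the reference
    simulation: 10,000 SNPs, 10% causal, U(0.05, 0.95) frequencies,
    mu ~ 0.9*delta0 + 0.1*N(0, 0.001*Ne), prevalence 1%, balanced training
    cohort and a 100+100 test set."""

    m: int = 10_000
    causal_prop: float = 0.1
    freq_dist: str = "uniform"          # "uniform" | "scaled-beta" | "custom"
    freq_params: tuple = (0.8, 0.8)
    freq_custom: np.ndarray | None = None
    effect_var_scale: float = 0.001
    kappa: float = 0.01
    n0_train: int = 1000
    n1_train: int = 1000
    n0_test: int = 100
    n1_test: int = 100
    divergence: Divergence | None = None
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.causal_prop <= 1:
            raise DataError("causal_prop must lie in [0, 1]")
        if not 0 < self.kappa < 1:
            raise DataError("kappa must lie in (0, 1)")
        if min(self.n0_train, self.n1_train, self.n0_test, self.n1_test) < 1:
            raise DataError("all sample counts must be >= 1")


@dataclass
class SimTruth:
    """Generative ground truth of one simulated study."""

    causal_ids: list
    true_mu: np.ndarray
    true_beta: np.ndarray
    f_pop: np.ndarray
    f1: np.ndarray

    def to_frame(self, snp_ids) -> "pd.DataFrame":
        import pandas as pd

        causal = np.isin(snp_ids, self.causal_ids)
        return pd.DataFrame({
            "snp_id": snp_ids, "causal": causal.astype(int),
            "true_mu": self.true_mu, "true_beta": self.true_beta,
            "f_pop": self.f_pop, "f1": self.f1,
        })


def sample_frequencies(dist, m: int, seed: int, params=(0.8, 0.8)) -> np.ndarray:
    """Reference-allele frequencies on (0.05, 0.95).

    ``uniform``: U(0.05, 0.95). ``scaled-beta``: 0.05 + 0.9*Beta(a, b) —
    Beta(1, 1) recovers the uniform. A vector passed as ``dist`` is returned
    as-is after range validation.
    """
    if isinstance(dist, (np.ndarray, list, tuple)) and not isinstance(dist, str):
        f = np.asarray(dist, dtype=float)
        if ((f <= _FREQ_LO - 1e-12) | (f >= _FREQ_HI + 1e-12)).any():
            raise DataError("custom frequencies must lie in (0.05, 0.95)")
        return f
    rng = np.random.default_rng(seed)
    if dist == "uniform":
        return rng.uniform(_FREQ_LO, _FREQ_HI, size=m)
    if dist == "scaled-beta":
        a, b = params
        if a <= 0 or b <= 0:
            raise DataError("Beta shape parameters must be positive")
        return _FREQ_LO + 0.9 * rng.beta(a, b, size=m)
    raise DataError(f"unknown frequency distribution {dist!r}")


def case_frequency(f0: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Case reference-allele frequency implied by the allelic log-OR:
    logit(f1) = logit(f0) + beta."""
    return f0 * np.exp(beta) / (1 - f0 + f0 * np.exp(beta))


def _sample_group(rng, n, f, block_size=1, rho=0.0) -> np.ndarray:
    """n x m dosages, Bin(2, f_j) per SNP; optional exchangeable-correlation
    blocks via a Gaussian copula on the two allele draws."""
    m = f.size
    out = np.empty((n, m), dtype=np.int8)
    if block_size <= 1 or rho == 0.0:
        for lo in range(0, n, _ROW_CHUNK):
            hi = min(lo + _ROW_CHUNK, n)
            out[lo:hi] = rng.binomial(2, f, size=(hi - lo, m)).astype(np.int8)
        return out
    sr = math.sqrt(rho)
    cr = math.sqrt(1 - rho)
    for lo in range(0, m, block_size):
        hi = min(lo + block_size, m)
        width = hi - lo
        dose = np.zeros((n, width), dtype=np.int8)
        for _allele in range(2):  # two independent allele draws per person
            shared = rng.standard_normal((n, 1))
            latent = sr * shared + cr * rng.standard_normal((n, width))
            dose += (stats.norm.cdf(latent) < f[lo:hi]).astype(np.int8)
        out[:, lo:hi] = dose
    return out


def simulate_case_control(config: SimConfig):
    """Draw (train, test, truth) for one independent-SNP study.

    Returns two labelled :class:`GenotypeData` cohorts sampled
    retrospectively from the per-group binomial genotype model, plus the
    generative :class:`SimTruth`.
    """
    ss = np.random.SeedSequence(config.seed)
    s_freq, s_mu, s_train, s_test, s_div = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]
    m = config.m
    dist = config.freq_custom if config.freq_dist == "custom" else config.freq_dist
    f_pop = sample_frequencies(
        dist, m, seed=s_freq.integers(2**31 - 1), params=config.freq_params
    )
    ne = effective_sample_size(config.n0_train, config.n1_train)

    n_causal = math.ceil(m * config.causal_prop) if config.causal_prop > 0 else 0
    causal = np.zeros(m, dtype=bool)
    if n_causal:
        causal[s_mu.choice(m, size=n_causal, replace=False)] = True
    mu = np.zeros(m)
    mu[causal] = s_mu.normal(0.0, math.sqrt(config.effect_var_scale * ne),
                             size=n_causal)
    se = np.sqrt(2.0 / (ne * f_pop * (1 - f_pop)))
    beta = mu * se
    f1 = case_frequency(f_pop, beta)

    snp_ids = [f"snp{i + 1}" for i in range(m)]
    ref = np.full(m, "A", dtype=object)
    alt = np.full(m, "G", dtype=object)

    def _make(rng, n0, n1, f0_g, f1_g, prefix):
        x0 = _sample_group(rng, n0, f0_g, config.ld_block_size, config.ld_rho)
        x1 = _sample_group(rng, n1, f1_g, config.ld_block_size, config.ld_rho)
        return GenotypeData(
            sample_ids=[f"{prefix}{i + 1}" for i in range(n0 + n1)],
            snp_ids=snp_ids,
            ref_alleles=ref, alt_alleles=alt,
            dosages=np.vstack([x0, x1]),
            phenotypes=np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)],
        )

    train = _make(s_train, config.n0_train, config.n1_train, f_pop, f1, "tr")

    f_pop_test, beta_test = f_pop, beta
    if config.divergence is not None:
        div = config.divergence
        if div.test_freq_dist is not None:
            f_pop_test = sample_frequencies(
                div.test_freq_dist, m,
                seed=int(s_div.integers(2**31 - 1)),
                params=div.test_freq_params,
            )
        if div.effect_shift_var_scale is not None:
            shift_mu = s_div.normal(
                0.0, math.sqrt(div.effect_shift_var_scale * ne), size=m
            )
            beta_test = beta + shift_mu * se
    f1_test = case_frequency(f_pop_test, beta_test)
    test = _make(s_test, config.n0_test, config.n1_test,
                 f_pop_test, f1_test, "te")

    truth = SimTruth(
        causal_ids=[snp_ids[i] for i in np.where(causal)[0]],
        true_mu=mu, true_beta=beta, f_pop=f_pop, f1=f1,
    )
    return train, test, truth


def simulate_phenotype_from_genotypes(
    genotypes: GenotypeData,
    causal_prop: float,
    beta_var: float,
    seed: int,
    target_case_fraction: float = 0.5,
):
    """Logistic phenotypes on existing genotypes.

    A random fraction ``causal_prop`` of SNPs receives log-ORs drawn from
    N(0, beta_var); ``y ~ Bernoulli(expit(sum_C beta_i x_i + b))`` with the
    intercept b solved by bisection so the expected case fraction matches the
    target. Returns ``(phenotypes, truth, info)`` where info reports the
    realized observed-scale heritability diagnostic
    ``var(g) / (var(g) + pi^2/3)``.
    """
    if genotypes.n_snps == 0 or genotypes.n_samples == 0:
        raise DataError("empty genotype matrix")
    rng = np.random.default_rng(seed)
    m = genotypes.n_snps
    n_causal = math.ceil(m * causal_prop) if causal_prop > 0 else 0
    causal = np.zeros(m, dtype=bool)
    if n_causal:
        causal[rng.choice(m, size=n_causal, replace=False)] = True
    beta = np.zeros(m)
    beta[causal] = rng.normal(0.0, math.sqrt(beta_var), size=n_causal) \
        if beta_var > 0 else 0.0
    g = genotypes.mean_imputed() @ beta

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(g + mid).mean() < target_case_fraction:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    y = (rng.random(genotypes.n_samples) < expit(g + b)).astype(int)

    obs = genotypes.dosages != -1
    xsum = np.where(obs, genotypes.dosages, 0).sum(axis=0)
    f_pop = xsum / np.maximum(2.0 * obs.sum(axis=0), 1.0)
    truth = SimTruth(
        causal_ids=[genotypes.snp_ids[i] for i in np.where(causal)[0]],
        true_mu=np.full(m, np.nan),
        true_beta=beta,
        f_pop=f_pop,
        f1=case_frequency(np.clip(f_pop, 1e-9, 1 - 1e-9), beta),
    )
    var_g = g.var()
    info = {
        "intercept": b,
        "case_fraction": float(y.mean()),
        "h2_observed": float(var_g / (var_g + np.pi**2 / 3.0)),
    }
    return y, truth, info


def make_fixture(config: SimConfig, outdir) -> dict:
    """Simulate a study and write the fixture files.

    Writes sumstats.tsv (training summaries via :func:`compute_sumstats`),
    test.geno.tsv, test.pheno.tsv, truth.tsv and a config.yaml echo; fully
    determined by ``config.seed``. Returns the file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    train, test, truth = simulate_case_control(config)
    ss = compute_sumstats(train)
    paths = {
        "sumstats": outdir / "sumstats.tsv",
        "geno": outdir / "test.geno.tsv",
        "pheno": outdir / "test.pheno.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_sumstats(ss, paths["sumstats"])
    write_genotypes(test, paths["geno"])
    write_phenotypes(test, paths["pheno"])
    truth.to_frame(train.snp_ids).to_csv(
        paths["truth"], sep="\t", index=False, float_format="%.17g"
    )
    cfg = asdict(config)
    cfg["divergence"] = None if config.divergence is None else asdict(config.divergence)
    cfg.pop("freq_custom", None)
    cfg["freq_params"] = list(cfg["freq_params"])
    if cfg["divergence"] is not None:
        cfg["divergence"]["test_freq_params"] = list(
            cfg["divergence"]["test_freq_params"]
        )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
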