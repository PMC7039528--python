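"""Polygenic risk scores and the Bayes-optimal classification rule.

For independent SNPs with genotype dosages x and per-SNP log-ORs beta, the
score ``S = sum_i beta_i x_i`` is the sufficient statistic of the posterior
log-odds of disease, and the risk-minimizing classifier under zero-one loss
predicts disease when

    S > -log(kappa/(1-kappa)) - 2 * sum_i log((1-f_i1)/(1-f_i0)),

where kappa is the disease prevalence and f_i0/f_i1 are the control/case
reference-allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import DataError
from .sumstats import GenotypeData

__all__ = ["ScoreResult", "DecisionConfig", "score", "classify",
           "bayes_threshold", "reconstruct_group_frequencies"]


@dataclass
class ScoreResult:
    sample_ids: list
    prs: np.ndarray
    weights_used: np.ndarray
    snp_ids: list

    @property
    def n_snps_used(self) -> int:
        return len(self.snp_ids)

    def to_frame(self, standardize: bool = False) -> pd.DataFrame:
        prs = self.prs
        if standardize:
            sd = prs.std(ddof=1)
            if sd == 0:
                raise DataError("cannot standardize constant scores")
            prs = (prs - prs.mean()) / sd
        return pd.DataFrame({"sample_id": self.sample_ids, "prs": prs})


@dataclass
class DecisionConfig:
    """Inputs of the optimal decision threshold."""

    kappa: float
    f0: np.ndarray
    f1: np.ndarray

    def __post_init__(self):
        self.f0 = np.atleast_1d(np.asarray(self.f0, dtype=float))
        self.f1 = np.atleast_1d(np.asarray(self.f1, dtype=float))
        if not 0 < self.kappa < 1:
            raise DataError("prevalence kappa must lie in (0, 1)")
        for name, f in (("f0", self.f0), ("f1", self.f1)):
            if ((f <= 0) | (f >= 1)).any():
                raise DataError(f"{name} frequencies must lie in (0, 1)")


def _weights_array(effects, snp_ids=None):
    """Accept PosteriorEffects, a weight DataFrame, or a bare vector."""
    if isinstance(effects, pd.DataFrame):
        wcol = next(
            (c for c in ("weight", "beta_tilde", "beta_hat") if c in effects), None
        )
        if wcol is None:
            raise DataError("weight table needs a weight/beta_tilde/beta_hat column")
        return list(effects["snp_id"]), effects[wcol].to_numpy(dtype=float)
    if hasattr(effects, "beta_tilde"):  # PosteriorEffects
        return list(effects.snp_ids), np.asarray(effects.beta_tilde, dtype=float)
    w = np.asarray(effects, dtype=float)
    return (list(snp_ids) if snp_ids is not None else None), w


def score(effects, genotypes: GenotypeData) -> ScoreResult:
    """S = sum_i w_i x_i with per-SNP mean imputation of missing dosages.

    Inputs are assumed harmonized (same SNPs referring to the same alleles);
    SNPs are aligned by identifier when the weight source carries snp_ids.
    """
    snp_ids, w = _weights_array(effects)
    if snp_ids is not None:
        pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
        keep = [(i, pos[s]) for i, s in enumerate(snp_ids) if s in pos]
        if not keep:
            raise DataError("no overlapping SNPs between weights and genotypes")
        widx, gidx = map(np.asarray, zip(*keep))
        w = w[widx]
        genotypes = genotypes.subset_snps(gidx)
        snp_ids = [snp_ids[i] for i in widx]
    else:
        if len(w) != genotypes.n_snps:
            raise DataError("weight vector length does not match SNP count")
        snp_ids = list(genotypes.snp_ids)
    x = genotypes.mean_imputed()
    prs = x @ w
    if not np.isfinite(prs).all():
        raise DataError("non-finite scores produced")
    return ScoreResult(
        sample_ids=list(genotypes.sample_ids),
        prs=prs,
        weights_used=w,
        snp_ids=snp_ids,
    )


def bayes_threshold(config: DecisionConfig) -> float:
    """Optimal score cutoff: -log(kappa/(1-kappa)) - 2*sum log((1-f1)/(1-f0))."""
    kap = config.kappa
    return float(
        -np.log(kap / (1 - kap))
        - 2.0 * np.sum(np.log((1 - config.f1) / (1 - config.f0)))
    )


def classify(scores: ScoreResult, config: DecisionConfig):
    """Zero-one-loss-optimal predictions: 1 iff PRS exceeds the threshold.

    Returns ``(predictions, threshold)``.
    """
    m = len(scores.weights_used)
    if config.f0.size not in (0, m) or config.f1.size not in (0, m):
        raise DataError(
            f"frequency vectors (len {config.f0.size}/{config.f1.size}) do not "
            f"match the {m} scored SNPs"
        )
    thr = bayes_threshold(config)
    return (scores.prs > thr).astype(int), thr


def reconstruct_group_frequencies(sumstats: pd.DataFrame):
    """Recover (f0, f1) from pooled frequency, beta_hat and the case fraction.

    With case fraction ``w = n1/(n0+n1)`` the pooled frequency is
    ``f = (1-w) f0 + w f1`` and ``logit(f1) = logit(f0) + beta_hat``; the pair
    is found per SNP by a monotone one-dimensional root solve in logit(f0).
    Used when classification is requested from summary statistics that lack
    the per-group frequencies.
    """
    from scipy.optimize import brentq
    from scipy.special import expit, logit

    f = sumstats["f"].to_numpy(dtype=float)
    beta = sumstats["beta_hat"].to_numpy(dtype=float)
    n0 = sumstats["n0"].to_numpy(dtype=float)
    n1 = sumstats["n1"].to_numpy(dtype=float)
    w = n1 / (n0 + n1)
    f0 = np.empty_like(f)
    for i in range(len(f)):
        def pooled(t, i=i):
            return (1 - w[i]) * expit(t) + w[i] * expit(t + beta[i]) - f[i]
        f0[i] = expit(brentq(pooled, -40.0, 40.0))
    f1 = expit(logit(f0) + beta)
    return f0, f1
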