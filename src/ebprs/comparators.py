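"""Alternative summary-statistics PRS methods used as benchmarks.

Five methods share the posterior-effects weight-table interface so that
scoring and evaluation are method-agnostic:

* unadjusted PRS — observed marginal log-ORs as weights;
* P+T — greedy LD clumping followed by p-value thresholding, with the
  cutoff tuned on labelled data;
* LDpred-inf — ridge posterior mean under an infinitesimal Gaussian model,
  on the standardized-genotype scale;
* So & Sham — Tweedie-corrected standardized effects converted to the square
  root of per-SNP explained liability, weighted by the local true discovery
  rate;
* Mak et al. — observed log-ORs weighted by the local true discovery rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DataError, NumericalError
from .effect_model import EffectSizeModel, ltdr
from .sumstats import GenotypeData, effective_sample_size

logger = logging.getLogger(__name__)

#: p-value grid used for P+T threshold tuning.
DEFAULT_P_GRID = (1.0, 5e-1, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6)


@dataclass
class PTConfig:
    r2_threshold: float = 0.1
    p_grid: tuple = DEFAULT_P_GRID
    window_kb: float | None = None

    def __post_init__(self):
        if not 0 < self.r2_threshold <= 1:
            raise DataError("r2_threshold must lie in (0, 1]")
        if any(not 0 < p <= 1 for p in self.p_grid):
            raise DataError("p_grid values must lie in (0, 1]")


@dataclass
class LDpredInfConfig:
    h2: float | None = None
    n: float | None = None
    ld_matrix: np.ndarray | None = None


@dataclass
class LindseyConfig:
    """Settings for the log-linear Poisson density fit used by Tweedie's
    formula: histogram bins over the data range padded 10%, fitted with a
    polynomial log-density."""

    bins: int = 120
    degree: int = 7
    pad: float = 0.10


def _weight_frame(sumstats: pd.DataFrame, weights: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"snp_id": sumstats["snp_id"], "weight": weights})


def unadjusted_weights(sumstats: pd.DataFrame) -> pd.DataFrame:
    """Observed marginal log-ORs, all SNPs."""
    return _weight_frame(sumstats, sumstats["beta_hat"].to_numpy(dtype=float))


def clump(
    sumstats: pd.DataFrame,
    genotypes: GenotypeData | None,
    config: PTConfig = PTConfig(),
) -> list:
    """Greedy LD clumping: repeatedly retain the most significant remaining
    SNP and discard remaining SNPs whose dosage r^2 with it exceeds the
    threshold. Ties on p break by lexicographic snp_id. Returns retained ids.

    SNPs without genotype columns are treated as uncorrelated (warned).
    """
    order = sumstats.sort_values(["p", "snp_id"], kind="mergesort")
    ids = order["snp_id"].tolist()
    if genotypes is None:
        return ids
    gpos = {s: j for j, s in enumerate(genotypes.snp_ids)}
    missing = [s for s in ids if s not in gpos]
    if missing:
        logger.warning(
            "%d SNPs lack genotypes; treated as uncorrelated in clumping",
            len(missing),
        )
    x = genotypes.mean_imputed()
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    norms[norms == 0] = np.inf  # constant column correlates with nothing
    pos_col = None
    if "pos" in sumstats.columns and config.window_kb is not None:
        pos_col = sumstats.set_index("snp_id")["pos"].to_dict()
    retained: list = []
    active = dict.fromkeys(ids)  # insertion-ordered "set"
    while active:
        lead = next(iter(active))
        del active[lead]
        retained.append(lead)
        if lead not in gpos:
            continue
        j = gpos[lead]
        r = (xc.T @ xc[:, j]) / (norms * norms[j])
        drop = []
        for s in active:
            if s not in gpos:
                continue
            if pos_col is not None:
                if abs(pos_col[s] - pos_col[lead]) > config.window_kb * 1000:
                    continue
            if r[gpos[s]] ** 2 > config.r2_threshold:
                drop.append(s)
        for s in drop:
            del active[s]
    return retained


def pt_weights(
    sumstats: pd.DataFrame, retained, p_cutoff: float
) -> pd.DataFrame:
    """beta_hat on retained SNPs passing the p-value cutoff, zero elsewhere."""
    retained = set(retained)
    in_set = sumstats["snp_id"].isin(retained).to_numpy()
    passed = sumstats["p"].to_numpy(dtype=float) <= p_cutoff
    w = np.where(in_set & passed, sumstats["beta_hat"].to_numpy(dtype=float), 0.0)
    if not w.any():
        logger.warning("no SNP passes p <= %g; all P+T weights are zero", p_cutoff)
    return _weight_frame(sumstats, w)


def pt_tune(
    sumstats: pd.DataFrame,
    genotypes: GenotypeData,
    config: PTConfig = PTConfig(),
    metric: str = "r2",
    clump_genotypes: GenotypeData | None = None,
):
    """Pick the p-value cutoff maximizing the metric on labelled tuning data.

    Ties break toward the larger (more inclusive) cutoff. Returns
    ``(best_cutoff, weights, per_cutoff_table)``.
    """
    from . import evaluate
    from .scoring import score

    if genotypes.phenotypes is None:
        raise DataError("pt_tune requires phenotypes on the tuning genotypes")
    retained = clump(sumstats, clump_genotypes, config)
    rows = []
    for cutoff in sorted(config.p_grid, reverse=True):  # larger cutoff first
        w = pt_weights(sumstats, retained, cutoff)
        if not w["weight"].to_numpy().any():
            val = -np.inf
        else:
            s = score(w, genotypes)
            if np.ptp(s.prs) == 0:
                val = -np.inf
            elif metric == "r2":
                val = evaluate.predictive_r2(s.prs, genotypes.phenotypes)
            elif metric == "auc":
                val = evaluate.auc(s.prs, genotypes.phenotypes).auc
            else:
                raise DataError(f"unknown tuning metric {metric!r}")
        rows.append((cutoff, val))
    table = pd.DataFrame(rows, columns=["p_cutoff", metric])
    best = table.loc[table[metric].idxmax(), "p_cutoff"]  # first max = largest
    return float(best), pt_weights(sumstats, retained, float(best)), table


def estimate_h2_aggregate(z: np.ndarray, n: float) -> float:
    """Crude SNP-heritability estimate from the mean z^2 inflation,
    ``m * (mean(z^2) - 1) / n``, clipped to [0.01, 0.9]."""
    z = np.asarray(z, dtype=float)
    m = z.size
    return float(min(0.9, max(0.01, m * (np.mean(z**2) - 1.0) / n)))


def ldpred_inf_weights(
    sumstats: pd.DataFrame, config: LDpredInfConfig = LDpredInfConfig()
) -> pd.DataFrame:
    """Infinitesimal-model ridge posterior means on the standardized scale.

    Solves ``(m/(n*h2) * I + D) w = beta_std`` where ``beta_std = z/sqrt(n)``
    are marginal effects of standardized genotypes and D is the LD
    (correlation) matrix, identity when not supplied. Score the returned
    weights against standardized dosages (:func:`standardized_scale_factors`).
    """
    z = sumstats["z"].to_numpy(dtype=float)
    m = z.size
    n = config.n
    if n is None:
        n0 = sumstats["n0"].to_numpy(dtype=float)
        n1 = sumstats["n1"].to_numpy(dtype=float)
        n = float(np.median(n0 + n1))
    h2 = config.h2 if config.h2 is not None else estimate_h2_aggregate(z, n)
    if h2 * n <= 0:
        raise DataError("h2 * n must be positive")
    beta_std = z / np.sqrt(n)
    lam = m / (n * h2)
    if config.ld_matrix is None:
        w = beta_std / (lam + 1.0)
    else:
        d = np.asarray(config.ld_matrix, dtype=float)
        if d.shape != (m, m):
            raise DataError("ld_matrix shape does not match SNP count")
        a = lam * np.eye(m) + d
        try:
            c = np.linalg.cholesky(a)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("LDpred-inf system is not positive definite") from exc
        w = np.linalg.solve(a, beta_std)
        del c
    return _weight_frame(sumstats, w)


def standardized_scale_factors(genotypes: GenotypeData) -> np.ndarray:
    """Per-SNP 1/sd of mean-imputed dosages; multiply standardized-scale
    weights by this to score raw dosages (metrics are affine-invariant)."""
    x = genotypes.mean_imputed()
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = np.inf
    return 1.0 / sd


def lindsey_density(
    z: np.ndarray, config: LindseyConfig = LindseyConfig()
):
    """Smooth density estimate of z by Lindsey's method.

    Histogram counts on an equal-width grid are fit by a Poisson log-linear
    model with a polynomial basis in z; returns callables ``(f, dlogf)`` for
    the normalized density and d/dz log f.
    """
    import statsmodels.api as sm

    z = np.asarray(z, dtype=float)
    lo, hi = z.min(), z.max()
    pad = config.pad * (hi - lo)
    edges = np.linspace(lo - pad, hi + pad, config.bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    scale = centers.std()
    center0 = centers.mean()
    t = (centers - center0) / scale
    basis = np.vander(t, config.degree + 1, increasing=True)
    fit = sm.GLM(counts, basis, family=sm.families.Poisson()).fit(maxiter=200)
    coef = fit.params
    dcoef = coef[1:] * np.arange(1, config.degree + 1)

    width = edges[1] - edges[0]
    tz = lambda x: (np.asarray(x, dtype=float) - center0) / scale

    def log_unnorm(x):
        return np.vander(tz(x), config.degree + 1, increasing=True) @ coef

    norm = np.sum(np.exp(log_unnorm(centers))) * width

    def f(x):
        return np.exp(log_unnorm(x)) / norm

    def dlogf(x):
        return (np.vander(tz(x), config.degree, increasing=True) @ dcoef) / scale

    if not np.isfinite(norm) or norm <= 0:
        raise NumericalError("Lindsey density fit failed to normalize")
    dens = f(z)
    if (dens <= 0).any() or not np.isfinite(dens).all():
        raise NumericalError("non-positive density estimate on the observed z-range")
    return f, dlogf


def tweedie_posterior_mean(
    z: np.ndarray, config: LindseyConfig = LindseyConfig()
) -> np.ndarray:
    """Nonparametric E(mu | z) = z + f'(z)/f(z) with f by Lindsey's method."""
    _, dlogf = lindsey_density(z, config)
    return np.asarray(z, dtype=float) + dlogf(z)


def so_weights(
    sumstats: pd.DataFrame,
    kappa: float,
    model: EffectSizeModel | None = None,
    density: LindseyConfig = LindseyConfig(),
) -> pd.DataFrame:
    """Square root of per-SNP explained liability, weighted by ltdr.

    The standardized effect is Tweedie-corrected, converted to observed-scale
    variance explained ``4*E(mu|z)^2 / Ne``, transformed to the liability
    scale using prevalence ``kappa`` and the study case fraction, then signed
    by z and weighted by the total local true discovery rate from the fitted
    mixture model (fitted here with defaults when not supplied).
    """
    if not 0 < kappa < 1:
        raise DataError("prevalence kappa must lie in (0, 1)")
    z = sumstats["z"].to_numpy(dtype=float)
    n0 = sumstats["n0"].to_numpy(dtype=float)
    n1 = sumstats["n1"].to_numpy(dtype=float)
    ne = effective_sample_size(n0, n1)
    if model is None:
        from .effect_model import em_fit
        model = em_fit(z, ne=float(np.median(ne)))
    mu_hat = tweedie_posterior_mean(z, density)
    ltdr_total = ltdr(z, model).sum(axis=1)
    v_obs = 4.0 * mu_hat**2 / ne
    case_frac = n1 / (n0 + n1)
    phi_t = stats.norm.pdf(stats.norm.isf(kappa))
    v_liab = v_obs * (kappa**2 * (1 - kappa) ** 2) / (
        phi_t**2 * case_frac * (1 - case_frac)
    )
    w = ltdr_total * np.sqrt(v_liab) * np.sign(z)
    return _weight_frame(sumstats, w)


def mak_weights(sumstats: pd.DataFrame, model: EffectSizeModel) -> pd.DataFrame:
    """Observed log-ORs shrunk by the total local true discovery rate."""
    z = sumstats["z"].to_numpy(dtype=float)
    w = ltdr(z, model).sum(axis=1) * sumstats["beta_hat"].to_numpy(dtype=float)
    return _weight_frame(sumstats, w)
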