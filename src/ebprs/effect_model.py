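"""Spike-and-slab mixture model on standardized GWAS effects.

The standardized effect of SNP i is ``mu_i = beta_i / se(beta_hat_i)``, so the
observed z-score satisfies ``Z_i | mu_i ~ N(mu_i, 1)``. Across SNPs the prior

    mu_i ~ pi_0 * delta_0 + sum_j pi_j * N(0, Ne * sigma_j^2),   j = 1..K

makes the marginal distribution of z a (K+1)-component Gaussian mixture with
component variances ``v_0 = 1`` (the null spike) and ``v_j = 1 + Ne*sigma_j^2``.
The ``Ne`` scaling keeps ``sigma_j^2`` invariant under changes of study size.

Fitting is MAP-EM with a Dirichlet pseudo-count ``alpha`` of extra null
observations, encoding the prior knowledge that most SNPs are not associated.
The posterior-mean log-OR used for scoring is the Bayes-risk-minimizing
estimator: per-component shrinkage ``Ne*sigma_j^2 / (1 + Ne*sigma_j^2)`` of
``beta_hat``, averaged with local-true-discovery-rate weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._exceptions import DataError, NumericalError

logger = logging.getLogger(__name__)

_V_FLOOR_EPS = 1e-8  # floor on v_j - 1, keeps sigma_j^2 > 0
_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class EffectSizeModel:
    """Fitted spike-and-slab mixture prior on standardized effects.

    pi has length K+1 (null first); sigma2 has length K with the per-SNP
    prior variance of mu in component j equal to ``ne * sigma2[j]``.
    """

    k: int
    pi: np.ndarray
    sigma2: np.ndarray
    ne: float
    alpha: float = 0.0
    loglik: float = np.nan
    n_iter: int = 0
    #: per-iteration penalized log-likelihood (not serialized)
    loglik_path: np.ndarray | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.pi) != self.k + 1 or len(self.sigma2) != self.k:
            raise DataError("pi must have length k+1 and sigma2 length k")
        if abs(self.pi.sum() - 1.0) > 1e-10 or (self.pi < 0).any():
            raise DataError("mixture proportions must be a probability vector")
        if (self.sigma2 <= 0).any():
            raise DataError("component variances must be positive")
        if self.ne <= 0:
            raise DataError("effective sample size must be positive")

    @property
    def v(self) -> np.ndarray:
        """Marginal z variances of the non-null components, 1 + ne*sigma2."""
        return 1.0 + self.ne * self.sigma2

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"k\t{self.k}\n")
            fh.write(f"ne\t{float(self.ne)!r}\n")
            fh.write(f"alpha\t{float(self.alpha)!r}\n")
            fh.write("pi\t" + "\t".join(repr(float(x)) for x in self.pi) + "\n")
            fh.write("sigma2\t" + "\t".join(repr(float(x)) for x in self.sigma2)
                     + "\n")
            fh.write(f"loglik\t{float(self.loglik)!r}\n")
            fh.write(f"n_iter\t{self.n_iter}\n")

    @classmethod
    def from_file(cls, path) -> "EffectSizeModel":
        fields = {}
        with open(path) as fh:
            for line in fh:
                key, *vals = line.rstrip("\n").split("\t")
                fields[key] = vals
        return cls(
            k=int(fields["k"][0]),
            pi=np.array([float(x) for x in fields["pi"]]),
            sigma2=np.array([float(x) for x in fields["sigma2"]]),
            ne=float(fields["ne"][0]),
            alpha=float(fields["alpha"][0]),
            loglik=float(fields["loglik"][0]),
            n_iter=int(fields["n_iter"][0]),
        )


@dataclass
class PosteriorEffects:
    """Per-SNP posterior quantities used as PRS weights."""

    snp_ids: list
    ltdr: np.ndarray          # m x K
    ltdr_total: np.ndarray    # m
    beta_tilde: np.ndarray    # m, posterior-mean log-OR

    def to_frame(self, sumstats: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"snp_id": self.snp_ids})
        if sumstats is not None:
            aligned = sumstats.set_index("snp_id").loc[self.snp_ids]
            out["beta_hat"] = aligned["beta_hat"].to_numpy()
            out["z"] = aligned["z"].to_numpy()
        out["ltdr_total"] = self.ltdr_total
        out["beta_tilde"] = self.beta_tilde
        return out


def _norm_logpdf(z: np.ndarray, var) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + np.square(z) / var)


def _component_logdens(z: np.ndarray, pi: np.ndarray, v: np.ndarray) -> np.ndarray:
    """m x (K+1) array of log(pi_j) + log f_j(z_i); v excludes the null."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    allv = np.concatenate(([1.0], v))
    with np.errstate(divide="ignore"):
        return np.log(pi)[None, :] + _norm_logpdf(z[:, None], allv[None, :])


def marginal_density(z, model: EffectSizeModel) -> np.ndarray:
    """Mixture marginal density of z: pi0*phi(z) + sum_j pi_j*phi(z; 0, v_j)."""
    model.validate()
    ld = _component_logdens(z, model.pi, model.v)
    out = np.exp(logsumexp(ld, axis=1))
    return out if np.ndim(z) else float(out[0])


def ltdr(z, model: EffectSizeModel) -> np.ndarray:
    """Local true discovery rates: P(component j | z_i), m x K.

    Rows sum with the null posterior probability to one.
    """
    model.validate()
    ld = _component_logdens(z, model.pi, model.v)
    log_marg = logsumexp(ld, axis=1, keepdims=True)
    resp = np.exp(ld - log_marg)
    return resp[:, 1:]


def posterior_mean_effect(
    sumstats: pd.DataFrame, model: EffectSizeModel
) -> PosteriorEffects:
    """Posterior-mean log-ORs: the EB-PRS weights.

    Under component j the posterior mean of beta given z is the linear
    shrinkage ``[ne*sigma_j^2 / (1 + ne*sigma_j^2)] * beta_hat``; the overall
    posterior mean averages these with ltdr weights (null contributes zero).
    """
    ne_data = None
    if {"n0", "n1"}.issubset(sumstats.columns):
        n0 = sumstats["n0"].to_numpy(dtype=float)
        n1 = sumstats["n1"].to_numpy(dtype=float)
        if np.isfinite(n0).all() and np.isfinite(n1).all():
            ne_data = float(np.median(4 * n0 * n1 / (n0 + n1)))
    if ne_data is not None and abs(ne_data - model.ne) > 0.01 * model.ne:
        logger.warning(
            "summary statistics Ne (%.1f) differs from model Ne (%.1f); "
            "sigma2 scaling makes the shrinkage explicit so scoring proceeds",
            ne_data, model.ne,
        )
    z = sumstats["z"].to_numpy(dtype=float)
    beta_hat = sumstats["beta_hat"].to_numpy(dtype=float)
    r = ltdr(z, model)
    shrink = (model.v - 1.0) / model.v  # ne*sigma2 / (1 + ne*sigma2)
    beta_tilde = beta_hat * (r @ shrink)
    return PosteriorEffects(
        snp_ids=list(sumstats["snp_id"]),
        ltdr=r,
        ltdr_total=r.sum(axis=1),
        beta_tilde=beta_tilde,
    )


def _penalized_loglik(z2, pi, v, alpha):
    ld = np.log(pi)[None, :] - 0.5 * (
        np.log(2.0 * np.pi * np.concatenate(([1.0], v)))[None, :]
        + z2[:, None] / np.concatenate(([1.0], v))[None, :]
    )
    ll = logsumexp(ld, axis=1).sum()
    if alpha > 0:
        ll += alpha * np.log(pi[0])
    return ll, ld


def em_fit(
    z,
    ne: float,
    k: int = 3,
    alpha: float | None = None,
    init: str = "default",
    tol: float = 1e-6,
    max_iter: int = 10_000,
    seed: int | None = None,
) -> EffectSizeModel:
    """MAP-EM fit of the (K+1)-component z-score mixture.

    Component 0 is fixed at variance 1 (the null); components j >= 1 have
    free variances ``v_j = 1 + ne*sigma_j^2 >= 1``. ``alpha`` adds a
    pseudo-count of null observations (default m/20). The penalized
    log-likelihood is non-decreasing across iterations; convergence is
    declared when its relative change drops below ``tol``.
    """
    z = np.asarray(z, dtype=float).ravel()
    m = z.size
    if m == 0:
        raise DataError("empty z vector")
    if not np.isfinite(z).all():
        raise DataError("non-finite z values")
    if k < 1:
        raise DataError("k must be >= 1")
    if alpha is None:
        alpha = m / 20.0
    if alpha < 0:
        raise DataError("alpha must be >= 0")
    z2 = np.square(z)

    pi = np.empty(k + 1)
    pi[0] = 0.95
    pi[1:] = 0.05 / k
    v_hi = max(4.0, float(np.quantile(z2, 0.99)))
    v = np.geomspace(1.5, v_hi, k)
    if init == "random":
        rng = np.random.default_rng(seed)
        v = v * np.exp(rng.normal(0, 0.1, size=k))

    ll_prev = -np.inf
    ll_path = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, ld = _penalized_loglik(z2, pi, v, alpha)
        ll_path.append(ll)
        if ll < ll_prev - 1e-9 * max(1.0, abs(ll_prev)):
            raise NumericalError(
                f"penalized log-likelihood decreased at iteration {n_iter}"
            )
        resp = np.exp(ld - logsumexp(ld, axis=1, keepdims=True))
        nj = resp.sum(axis=0)
        pi = nj / (m + alpha)
        pi[0] = (nj[0] + alpha) / (m + alpha)
        with np.errstate(invalid="ignore", divide="ignore"):
            v_new = (resp[:, 1:] * z2[:, None]).sum(axis=0) / nj[1:]
        v = np.where(nj[1:] > 0, v_new, v)
        v = np.maximum(v, 1.0 + _V_FLOOR_EPS)
        if ll - ll_prev < tol * max(1.0, abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    order = np.argsort(v)
    v = v[order]
    pi = np.concatenate(([pi[0]], pi[1:][order]))
    ll_final, _ = _penalized_loglik(z2, pi, v, alpha)
    return EffectSizeModel(
        k=k,
        pi=pi,
        sigma2=(v - 1.0) / ne,
        ne=ne,
        alpha=alpha,
        loglik=float(ll_final),
        n_iter=n_iter,
        loglik_path=np.asarray(ll_path),
    )


def sample_z(model: EffectSizeModel, m: int, seed: int) -> np.ndarray:
    """Parametric draw of m z-scores from the fitted mixture marginal."""
    if m <= 0:
        raise DataError("m must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(model.k + 1, size=m, p=model.pi)
    sd = np.sqrt(np.concatenate(([1.0], model.v)))
    return rng.standard_normal(m) * sd[labels]


def _param_vector(model: EffectSizeModel) -> np.ndarray:
    return np.concatenate((model.pi, model.sigma2))


def select_alpha(
    z,
    ne: float,
    k: int = 3,
    alpha_grid=None,
    n_boot: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
):
    """Parametric-bootstrap selection of the Dirichlet pseudo-count.

    Fits a preliminary model at ``alpha = m/20``, simulates ``n_boot``
    z-vectors from it, refits every grid alpha on each replicate, and picks
    the alpha minimizing the mean relative error of the refitted (pi, sigma2)
    against the preliminary values. Returns ``(alpha, diagnostics)``.
    """
    z = np.asarray(z, dtype=float).ravel()
    m = z.size
    if alpha_grid is None:
        alpha_grid = [m / 100, m / 50, m / 20, m / 10, m / 5]
    alpha_grid = list(alpha_grid)
    if len(alpha_grid) == 0:
        raise DataError("empty alpha grid")
    if n_boot < 2:
        raise DataError("n_boot must be >= 2")
    prelim = em_fit(z, ne=ne, k=k, alpha=m / 20.0, tol=tol, max_iter=max_iter)
    theta0 = _param_vector(prelim)
    eps = 1e-8
    rng = np.random.default_rng(seed)
    boot_seeds = rng.integers(0, 2**31 - 1, size=n_boot)
    errors = np.zeros((len(alpha_grid), n_boot))
    for b, bs in enumerate(boot_seeds):
        zb = sample_z(prelim, m, seed=int(bs))
        for a, alpha in enumerate(alpha_grid):
            fit = em_fit(zb, ne=ne, k=k, alpha=alpha, tol=tol, max_iter=max_iter)
            theta = _param_vector(fit)
            errors[a, b] = np.mean(np.abs(theta - theta0) / (np.abs(theta0) + eps))
    mean_err = errors.mean(axis=1)
    best = int(np.argmin(mean_err))
    diagnostics = {
        "alpha_grid": alpha_grid,
        "mean_relative_error": mean_err,
        "preliminary_model": prelim,
    }
    return alpha_grid[best], diagnostics


def train(
    sumstats: pd.DataFrame,
    k: int = 3,
    alpha: float | str = "default",
    select: bool = False,
    n_boot: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
):
    """Fit the effect-size model from a summary-statistics table and return
    ``(model, posterior_effects)``.

    ``alpha='default'`` uses the preliminary pseudo-count m/20;
    ``select=True`` runs parametric-bootstrap alpha selection first.
    """
    need = {"z", "beta_hat", "n0", "n1"}
    if not need.issubset(sumstats.columns):
        raise DataError(f"summary statistics must contain columns {sorted(need)}")
    n0 = sumstats["n0"].to_numpy(dtype=float)
    n1 = sumstats["n1"].to_numpy(dtype=float)
    if not (np.isfinite(n0).all() and np.isfinite(n1).all()):
        raise DataError("n0/n1 required to compute the effective sample size")
    ne = float(np.median(4 * n0 * n1 / (n0 + n1)))
    z = sumstats["z"].to_numpy(dtype=float)
    m = z.size
    if select:
        alpha_val, _ = select_alpha(z, ne=ne, k=k, n_boot=n_boot, seed=seed,
                                    tol=tol, max_iter=max_iter)
    elif alpha == "default":
        alpha_val = m / 20.0
    else:
        alpha_val = float(alpha)
    model = em_fit(z, ne=ne, k=k, alpha=alpha_val, tol=tol,
                   max_iter=max_iter, seed=seed)
    effects = posterior_mean_effect(sumstats, model)
    return model, effects
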