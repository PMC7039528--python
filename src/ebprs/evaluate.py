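"""Prediction metrics and significance tests for comparing PRS methods.

Predictive r^2 is the squared Pearson correlation between scores and the
observed 0/1 phenotype; AUC is the Mann-Whitney estimator (ties count one
half). Two comparison procedures are provided: a stratified paired bootstrap
of the AUC difference, and a nested-logistic likelihood-ratio test of whether
one score adds predictive information over another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DataError, NumericalError
from .sumstats import GenotypeData, compute_sumstats

__all__ = [
    "EvalResult", "predictive_r2", "auc", "evaluate_scores",
    "auc_bootstrap_test", "nested_lrt", "crossval_benchmark",
]


@dataclass
class EvalResult:
    r2: float
    auc: float
    roc: np.ndarray  # (n_points, 2) ordered (fpr, tpr)
    n_case: int
    n_control: int


def _check_binary(phenotypes) -> np.ndarray:
    y = np.asarray(phenotypes, dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise DataError("phenotypes must be binary 0/1")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise DataError("both phenotype classes must be present")
    return y


def predictive_r2(scores, phenotypes) -> float:
    """Squared Pearson correlation between scores and the 0/1 phenotype."""
    s = np.asarray(scores, dtype=float)
    y = _check_binary(phenotypes)
    if np.ptp(s) == 0:
        raise DataError("scores are constant; r2 undefined")
    r = np.corrcoef(s, y)[0, 1]
    return float(r * r)


def _mann_whitney_auc(s: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(s)  # midranks: ties count 1/2 automatically
    n1 = int((y == 1).sum())
    n0 = y.size - n1
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _roc_points(s: np.ndarray, y: np.ndarray) -> np.ndarray:
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # collapse tied thresholds
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps, fps = tps[distinct], fps[distinct]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return np.column_stack([fpr, tpr])


def auc(scores, phenotypes) -> EvalResult:
    """Mann-Whitney AUC with the ROC curve from a full threshold sweep."""
    s = np.asarray(scores, dtype=float)
    y = _check_binary(phenotypes)
    roc = _roc_points(s, y)
    if (np.diff(roc, axis=0) < 0).any():
        raise NumericalError("ROC coordinates are not monotone")
    a = _mann_whitney_auc(s, y)
    return EvalResult(
        r2=np.nan, auc=a, roc=roc,
        n_case=int((y == 1).sum()), n_control=int((y == 0).sum()),
    )


def evaluate_scores(scores, phenotypes) -> EvalResult:
    """Both metrics on one score vector."""
    res = auc(scores, phenotypes)
    res.r2 = predictive_r2(scores, phenotypes)
    return res


def auc_bootstrap_test(
    scores_a, scores_b, phenotypes, n_boot: int = 2000, seed: int = 0
) -> dict:
    """Paired stratified bootstrap of delta-AUC = AUC(a) - AUC(b).

    Cases and controls are resampled within class; both scores are evaluated
    on the same resample. The two-sided p-value uses the normal approximation
    ``delta / sd_boot``; a percentile CI is also reported.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _check_binary(phenotypes)
    if a.shape != b.shape or a.shape != y.shape:
        raise DataError("score and phenotype vectors must have equal length")
    if n_boot < 100:
        raise DataError("n_boot must be >= 100")
    delta_obs = _mann_whitney_auc(a, y) - _mann_whitney_auc(b, y)
    rng = np.random.default_rng(seed)
    idx1 = np.where(y == 1)[0]
    idx0 = np.where(y == 0)[0]
    deltas = np.empty(n_boot)
    for t in range(n_boot):
        take = np.r_[rng.choice(idx1, size=idx1.size, replace=True),
                     rng.choice(idx0, size=idx0.size, replace=True)]
        yb = y[take]
        deltas[t] = _mann_whitney_auc(a[take], yb) - _mann_whitney_auc(b[take], yb)
    sd = deltas.std(ddof=1)
    if sd == 0:
        p = 1.0 if delta_obs == 0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta_obs) / sd))
    ci = tuple(np.percentile(deltas, [2.5, 97.5]))
    return {"delta_auc": delta_obs, "p": p, "ci": ci, "sd_boot": float(sd)}


def nested_lrt(scores_a, scores_b, phenotypes) -> dict:
    """Likelihood-ratio test of y ~ a  vs  y ~ a + b against chi^2(1).

    Tests whether score b adds predictive information over score a.
    """
    import statsmodels.api as sm

    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _check_binary(phenotypes)
    x_red = sm.add_constant(a)
    x_full = sm.add_constant(np.column_stack([a, b]))
    try:
        fit_red = sm.Logit(y, x_red).fit(disp=0, maxiter=200)
        fit_full = sm.Logit(y, x_full).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation and friends
        raise NumericalError(f"logistic fit failed: {exc}") from exc
    if not (np.isfinite(fit_red.llf) and np.isfinite(fit_full.llf)):
        raise NumericalError("logistic fit did not converge")
    stat = max(0.0, 2.0 * (fit_full.llf - fit_red.llf))
    return {"stat": float(stat), "p": float(stats.chi2.sf(stat, df=1))}


# ---------------------------------------------------------------------------
# Method dispatch + cross-validated benchmark

ALL_METHODS = ("ebprs", "unadj", "pt", "ldpred-inf", "so", "mak")


def method_weights(
    name: str,
    sumstats: pd.DataFrame,
    tune_genotypes: GenotypeData | None = None,
    kappa: float = 0.01,
    clump_genotypes: GenotypeData | None = None,
    model=None,
    h2: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Weight table (snp_id, weight) for any implemented method.

    ``pt`` needs labelled tuning genotypes; ``ldpred-inf`` returns weights on
    the standardized-genotype scale (callers rescale by
    :func:`ebprs.comparators.standardized_scale_factors`, flagged by the
    ``standardized`` attribute on the returned frame).
    """
    from . import comparators, effect_model

    def _fit_model():
        nonlocal model
        if model is None:
            model, effects = effect_model.train(sumstats, seed=seed)
            return model, effects
        return model, effect_model.posterior_mean_effect(sumstats, model)

    if name == "ebprs":
        _, effects = _fit_model()
        out = pd.DataFrame({"snp_id": effects.snp_ids,
                            "weight": effects.beta_tilde})
    elif name == "unadj":
        out = comparators.unadjusted_weights(sumstats)
    elif name == "pt":
        if tune_genotypes is None:
            raise DataError("P+T requires labelled tuning genotypes")
        _, out, _ = comparators.pt_tune(
            sumstats, tune_genotypes, clump_genotypes=clump_genotypes
        )
    elif name == "ldpred-inf":
        out = comparators.ldpred_inf_weights(
            sumstats, comparators.LDpredInfConfig(h2=h2)
        )
        out.attrs["standardized"] = True
        return out
    elif name == "so":
        mdl, _ = _fit_model()
        out = comparators.so_weights(sumstats, kappa=kappa, model=mdl)
    elif name == "mak":
        mdl, _ = _fit_model()
        out = comparators.mak_weights(sumstats, mdl)
    else:
        raise DataError(f"unknown method {name!r}")
    out.attrs["standardized"] = False
    return out


def score_with_weights(weights: pd.DataFrame, genotypes: GenotypeData):
    """Score genotypes, rescaling standardized-scale weights when flagged."""
    from .comparators import standardized_scale_factors
    from .scoring import score

    if weights.attrs.get("standardized"):
        scale = pd.Series(
            standardized_scale_factors(genotypes), index=genotypes.snp_ids
        )
        weights = weights.copy()
        weights["weight"] = (
            weights["weight"].to_numpy()
            * scale.reindex(weights["snp_id"]).fillna(0.0).to_numpy()
        )
    return score(weights, genotypes)


def crossval_benchmark(
    genotypes: GenotypeData,
    methods=ALL_METHODS,
    k_folds: int = 5,
    seed: int = 0,
    kappa: float = 0.01,
    use_ld: bool = False,
):
    """Stratified k-fold cross-validated comparison of PRS methods.

    Per fold, summary statistics are computed on the training folds only,
    each method derives its weights from them (P+T additionally tunes its
    cutoff on the training folds), and the held-out fold is scored. Returns
    ``(per_fold_table, summary_table)`` with r2 and AUC.
    """
    from sklearn.model_selection import StratifiedKFold

    if genotypes.phenotypes is None:
        raise DataError("crossval_benchmark requires phenotypes")
    y = genotypes.phenotypes
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        train = genotypes.subset_samples(tr_idx)
        test = genotypes.subset_samples(te_idx)
        if len(set(test.phenotypes)) < 2 or len(set(train.phenotypes)) < 2:
            raise DataError(f"fold {fold} contains a single phenotype class")
        ss = compute_sumstats(train)
        for name in methods:
            w = method_weights(
                name, ss,
                tune_genotypes=train,
                clump_genotypes=train if use_ld else None,
                kappa=kappa,
                seed=seed,
            )
            res = evaluate_scores(
                score_with_weights(w, test).prs, test.phenotypes
            )
            rows.append({
                "method": name, "fold": fold,
                "r2": res.r2, "auc": res.auc,
            })
    per_fold = pd.DataFrame(rows)
    summary = (
        per_fold.groupby("method", sort=False)[["r2", "auc"]]
        .agg(["mean", "std"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    return per_fold, summary.reset_index()
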