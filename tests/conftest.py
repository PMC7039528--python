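import numpy as np
import pandas as pd
import pytest

from ebprs import SimConfig, compute_sumstats, simulate_case_control
from ebprs.effect_model import EffectSizeModel
from ebprs.sumstats import GenotypeData


@pytest.fixture(scope="session")
def small_study():
    """One seeded independent-SNP study, reused across read-only tests."""
    cfg = SimConfig(m=1500, n0_train=1000, n1_train=1000,
                    n0_test=100, n1_test=100, seed=42)
    train, test, truth = simulate_case_control(cfg)
    return train, test, truth


@pytest.fixture(scope="session")
def small_sumstats(small_study):
    train, _, _ = small_study
    return compute_sumstats(train)


@pytest.fixture()
def two_component_model():
    return EffectSizeModel(k=2, pi=np.array([0.9, 0.07, 0.03]),
                           sigma2=np.array([0.002, 0.01]), ne=1000.0)


def make_genotypes(dosages, snp_ids=None, phenotypes=None, ref=None, alt=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    return GenotypeData(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=snp_ids or [f"snp{j}" for j in range(m)],
        ref_alleles=np.asarray(ref if ref is not None else ["A"] * m, dtype=object),
        alt_alleles=np.asarray(alt if alt is not None else ["G"] * m, dtype=object),
        dosages=dosages,
        phenotypes=phenotypes,
    )


def sumstats_frame(**cols):
    """Minimal valid summary-statistics frame for unit tests."""
    m = len(next(iter(cols.values())))
    base = {
        "snp_id": [f"snp{j}" for j in range(m)],
        "ref_allele": ["A"] * m,
        "alt_allele": ["G"] * m,
        "n0": [1000] * m,
        "n1": [1000] * m,
        "f": [0.5] * m,
        "f0": [np.nan] * m,
        "f1": [np.nan] * m,
    }
    base.update(cols)
    df = pd.DataFrame(base)
    if "se" not in df:
        df["se"] = 0.1
    if "beta_hat" not in df and "z" in df:
        df["beta_hat"] = df["z"] * df["se"]
    if "z" not in df:
        df["z"] = df["beta_hat"] / df["se"]
    if "p" not in df:
        from scipy import stats
        df["p"] = 2 * stats.norm.sf(np.abs(df["z"]))
    return df
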