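"""Reading, writing, validation and harmonization of GWAS summary statistics
and individual-level genotypes.

Conventions used throughout the package:

* Effects are log odds ratios (natural log) per copy of the declared
  *reference allele*; ``z = beta_hat / se``.
* Genotype dosages count copies of the reference allele, so entries are
  0, 1, 2 or :data:`MISSING` (``-1``).
* The effective sample size of a case-control study with ``n0`` controls and
  ``n1`` cases is ``Ne = 4*n0*n1/(n0+n1)``, and the standard error of the
  allelic log-OR under the null is ``sqrt(2 / (Ne * f * (1 - f)))`` with
  ``f`` the pooled reference-allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DataError

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype dosage.
MISSING = -1

#: Canonical summary-statistics columns, in output order.
SUMSTATS_COLUMNS = [
    "snp_id", "ref_allele", "alt_allele", "n0", "n1",
    "f", "f0", "f1", "beta_hat", "se", "z", "p",
]

#: Default header-name aliases accepted by :func:`read_sumstats`.
DEFAULT_COLUMN_MAP = {
    "snp_id": "snp_id", "a1": "ref_allele", "a2": "alt_allele",
    "beta": "beta_hat", "or": "odds_ratio", "se": "se", "p": "p",
    "z": "z", "frq": "f", "f0": "f0", "f1": "f1", "n0": "n0", "n1": "n1",
    # canonical names map to themselves
    "ref_allele": "ref_allele", "alt_allele": "alt_allele",
    "beta_hat": "beta_hat", "f": "f",
}

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


def effective_sample_size(n0, n1):
    """``Ne = 4*n0*n1/(n0+n1)``: the balanced-design-equivalent sample size."""
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    return 4.0 * n0 * n1 / (n0 + n1)


@dataclass
class GenotypeData:
    """Individuals x SNPs dosage matrix with declared reference alleles.

    ``dosages[i, j]`` counts copies of ``ref_alleles[j]`` carried by sample
    ``sample_ids[i]``; missing calls are :data:`MISSING`.
    """

    sample_ids: list
    snp_ids: list
    ref_alleles: np.ndarray
    dosages: np.ndarray
    alt_alleles: np.ndarray | None = None
    phenotypes: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.ref_alleles = np.asarray(self.ref_alleles, dtype=object)
        if self.alt_alleles is not None:
            self.alt_alleles = np.asarray(self.alt_alleles, dtype=object)
        if self.phenotypes is not None:
            self.phenotypes = np.asarray(self.phenotypes, dtype=int)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise DataError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DataError("duplicate snp_ids in genotype data")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample_ids in genotype data")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError(
                f"{int(bad.sum())} dosage entries outside {{0,1,2,missing}}"
            )
        if self.phenotypes is not None:
            if len(self.phenotypes) != len(self.sample_ids):
                raise DataError("phenotype length does not match sample count")
            if not np.isin(self.phenotypes, (0, 1)).all():
                raise DataError("phenotypes must be binary 0/1")

    def subset_snps(self, index: np.ndarray) -> "GenotypeData":
        """New object restricted (and reordered) to SNP positions ``index``."""
        return GenotypeData(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in index],
            ref_alleles=self.ref_alleles[index],
            dosages=self.dosages[:, index],
            alt_alleles=None if self.alt_alleles is None else self.alt_alleles[index],
            phenotypes=self.phenotypes,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeData":
        """New object restricted (and reordered) to sample positions ``index``."""
        index = np.asarray(index)
        return GenotypeData(
            sample_ids=[self.sample_ids[i] for i in index],
            snp_ids=list(self.snp_ids),
            ref_alleles=self.ref_alleles,
            dosages=self.dosages[index],
            alt_alleles=self.alt_alleles,
            phenotypes=None if self.phenotypes is None else self.phenotypes[index],
        )

    def mean_imputed(self) -> np.ndarray:
        """Float dosage matrix with missing entries replaced per-SNP by the
        mean observed dosage (0 if a SNP is entirely missing)."""
        x = self.dosages.astype(float)
        miss = x == MISSING
        if not miss.any():
            return x
        x[miss] = np.nan
        col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(x))
        x[idx] = col_mean[idx[1]]
        return x


def validate_sumstats(df: pd.DataFrame, log=None) -> pd.DataFrame:
    """Drop rows violating the summary-statistics invariants; log the count.

    Invariants: finite beta_hat/se/z, ``se > 0``, ``0 < f < 1`` (when
    present), ``n0, n1 >= 1``, distinct alleles, unique snp_id (first kept),
    and ``z == beta_hat/se`` to 1e-10 where all three are present.
    """
    log = log or logger
    n_in = len(df)
    keep = np.ones(n_in, dtype=bool)
    keep &= df["se"].to_numpy() > 0
    for col in ("beta_hat", "se", "z"):
        keep &= np.isfinite(df[col].to_numpy(dtype=float))
    if "f" in df and df["f"].notna().any():
        f = df["f"].to_numpy(dtype=float)
        keep &= np.isnan(f) | ((f > 0) & (f < 1))
    for col in ("n0", "n1"):
        if col in df and df[col].notna().any():
            keep &= df[col].to_numpy(dtype=float) >= 1
    keep &= df["ref_allele"].to_numpy() != df["alt_allele"].to_numpy()
    with np.errstate(invalid="ignore"):
        resid = np.abs(
            df["z"].to_numpy(dtype=float)
            - df["beta_hat"].to_numpy(dtype=float) / df["se"].to_numpy(dtype=float)
        )
    keep &= ~(resid > 1e-10 * np.maximum(1.0, np.abs(df["z"].to_numpy(dtype=float))))
    out = df.loc[keep]
    dup = out["snp_id"].duplicated(keep="first")
    if dup.any():
        log.warning("dropping %d duplicated snp_id rows", int(dup.sum()))
        out = out.loc[~dup]
    n_dropped = n_in - len(out)
    if n_dropped:
        log.warning("dropped %d/%d rows failing invariants", n_dropped, n_in)
    if len(out) == 0:
        raise DataError("all summary-statistics rows failed validation")
    return out.reset_index(drop=True)


def read_sumstats(path, column_map: dict | None = None, log=None) -> pd.DataFrame:
    """Read a tab-separated summary-statistics table.

    Missing derived fields are reconstructed: beta from OR; z from beta/se,
    or from p (``|z| = Phi^{-1}(1-p/2)`` signed by beta); se from beta/z;
    p from z. Rows failing invariants are dropped with a logged count.
    """
    log = log or logger
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:  # noqa: BLE001 - rewrap for CLI exit codes
        raise DataError(f"cannot read summary statistics from {path}: {exc}") from exc
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update({k.lower(): v for k, v in column_map.items()})
    df = df.rename(columns={c: cmap.get(c.lower(), c.lower()) for c in df.columns})
    if "snp_id" not in df:
        raise DataError("no snp_id column found")
    if "odds_ratio" in df and "beta_hat" not in df:
        df["beta_hat"] = np.log(df["odds_ratio"].astype(float))
    has = df.columns
    if "beta_hat" not in has and "z" in has and "se" in has:
        df["beta_hat"] = df["z"].astype(float) * df["se"].astype(float)
    if "beta_hat" not in has:
        raise DataError("no usable effect column (beta, or, or z+se)")
    beta = df["beta_hat"].to_numpy(dtype=float)
    if "se" not in df.columns:
        if "z" in df.columns:
            with np.errstate(divide="ignore", invalid="ignore"):
                df["se"] = beta / df["z"].to_numpy(dtype=float)
        elif "p" in df.columns:
            zabs = stats.norm.isf(df["p"].to_numpy(dtype=float) / 2.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                df["se"] = np.abs(beta) / zabs
        else:
            raise DataError("cannot derive se: need se, z, or p")
    if "z" not in df.columns:
        if "p" in df.columns and (df["se"].isna()).all():
            zabs = stats.norm.isf(df["p"].to_numpy(dtype=float) / 2.0)
            df["z"] = np.sign(beta) * zabs
        else:
            df["z"] = beta / df["se"].to_numpy(dtype=float)
    if "p" not in df.columns:
        df["p"] = 2.0 * stats.norm.sf(np.abs(df["z"].to_numpy(dtype=float)))
    for col in ("ref_allele", "alt_allele"):
        if col not in df.columns:
            raise DataError(f"missing allele column ({col})")
        df[col] = df[col].astype(str).str.upper()
    for col in ("f", "f0", "f1", "n0", "n1"):
        if col not in df.columns:
            df[col] = np.nan
    df["snp_id"] = df["snp_id"].astype(str)
    df = df[SUMSTATS_COLUMNS + [c for c in df.columns if c not in SUMSTATS_COLUMNS]]
    return validate_sumstats(df, log=log)


def write_sumstats(df: pd.DataFrame, path) -> None:
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.17g")


def compute_sumstats(genotypes: GenotypeData) -> pd.DataFrame:
    """Per-SNP allelic association summaries from labelled genotypes.

    f0/f1 are reference-allele counts over ``2 * n_non_missing`` in
    controls/cases; ``beta_hat = log[f1(1-f0) / (f0(1-f1))]``;
    ``se = sqrt(2/(Ne*f*(1-f)))`` with pooled f. A Haldane-Anscombe
    continuity correction (+0.5 per allele-count cell) is applied to any SNP
    with a zero cell, flagged in the ``cc`` column.
    """
    if genotypes.phenotypes is None:
        raise DataError("compute_sumstats requires phenotypes")
    y = genotypes.phenotypes
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise DataError("need both cases and controls")
    x = genotypes.dosages
    obs = x != MISSING
    xv = np.where(obs, x, 0).astype(float)

    def _counts(mask):
        ref = (xv[mask] * obs[mask]).sum(axis=0)          # reference alleles
        tot = 2.0 * obs[mask].sum(axis=0)                  # total alleles
        return ref, tot - ref

    a0_ref, a0_alt = _counts(y == 0)
    a1_ref, a1_alt = _counts(y == 1)
    cc = (a0_ref == 0) | (a0_alt == 0) | (a1_ref == 0) | (a1_alt == 0)
    corr = np.where(cc, 0.5, 0.0)
    c0r, c0a = a0_ref + corr, a0_alt + corr
    c1r, c1a = a1_ref + corr, a1_alt + corr
    f0 = c0r / (c0r + c0a)
    f1 = c1r / (c1r + c1a)
    f = (c0r + c1r) / (c0r + c0a + c1r + c1a)
    beta = np.log(f1 * (1 - f0)) - np.log(f0 * (1 - f1))
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    ne = effective_sample_size(n0, n1)
    se = np.sqrt(2.0 / (ne * f * (1 - f)))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "snp_id": genotypes.snp_ids,
        "ref_allele": genotypes.ref_alleles,
        "alt_allele": (genotypes.alt_alleles
                       if genotypes.alt_alleles is not None
                       else np.full(genotypes.n_snps, "N", dtype=object)),
        "n0": n0, "n1": n1,
        "f": f, "f0": f0, "f1": f1,
        "beta_hat": beta, "se": se, "z": z, "p": p,
        "cc": cc,
    })


@dataclass
class HarmonizeReport:
    n_train: int
    n_test: int
    n_kept: int
    n_flipped: int
    n_dropped_palindromic: int
    n_dropped_mismatch: int


def harmonize(
    train: pd.DataFrame,
    test: GenotypeData,
    drop_palindromic: bool = True,
):
    """Align a summary-statistics table with test genotypes by snp_id.

    Where the test reference allele equals the training alternate allele the
    test dosages are recoded ``2 - x`` (sign-preserving). Strand-ambiguous
    palindromic SNPs (A/T, C/G) are dropped unless ``drop_palindromic`` is
    False. Returns ``(train_aligned, test_aligned, report)``.
    """
    test_pos = {s: i for i, s in enumerate(test.snp_ids)}
    train = train.loc[train["snp_id"].isin(test_pos)].reset_index(drop=True)
    if len(train) == 0:
        raise DataError("empty intersection between train and test SNPs")
    keep_rows, test_idx, flip = [], [], []
    n_pal = n_mis = 0
    for row in train.itertuples(index=True):
        ra, aa = row.ref_allele, row.alt_allele
        if drop_palindromic and frozenset((ra, aa)) in _PALINDROMIC:
            n_pal += 1
            continue
        j = test_pos[row.snp_id]
        t_ref = test.ref_alleles[j]
        if t_ref == ra:
            flip.append(False)
        elif t_ref == aa:
            flip.append(True)
        else:
            n_mis += 1
            continue
        keep_rows.append(row.Index)
        test_idx.append(j)
    if not keep_rows:
        raise DataError("empty intersection after allele harmonization")
    train_out = train.loc[keep_rows].reset_index(drop=True)
    geno = test.subset_snps(np.asarray(test_idx))
    flip = np.asarray(flip)
    if flip.any():
        d = geno.dosages.copy()
        obsv = d != MISSING
        cols = np.where(flip)[0]
        d[:, cols] = np.where(obsv[:, cols], 2 - d[:, cols], MISSING)
        geno = replace(
            geno,
            dosages=d,
            ref_alleles=np.where(flip, train_out["ref_allele"].to_numpy(object),
                                 geno.ref_alleles),
        )
    report = HarmonizeReport(
        n_train=len(train), n_test=len(test_pos), n_kept=len(train_out),
        n_flipped=int(flip.sum()), n_dropped_palindromic=n_pal,
        n_dropped_mismatch=n_mis,
    )
    logger.info(
        "harmonize: kept %d (flipped %d), dropped %d palindromic, %d mismatched",
        report.n_kept, report.n_flipped, n_pal, n_mis,
    )
    return train_out, geno, report


# ---------------------------------------------------------------------------
# Genotype I/O: plain TSV and PLINK bed/bim/fam


def write_genotypes(geno: GenotypeData, path) -> None:
    """Samples x SNPs TSV; allele metadata in leading ``#`` lines."""
    with open(path, "w") as fh:
        fh.write("#ref_alleles\t" + "\t".join(map(str, geno.ref_alleles)) + "\n")
        if geno.alt_alleles is not None:
            fh.write("#alt_alleles\t" + "\t".join(map(str, geno.alt_alleles)) + "\n")
        fh.write("sample_id\t" + "\t".join(map(str, geno.snp_ids)) + "\n")
        for i, sid in enumerate(geno.sample_ids):
            fh.write(str(sid) + "\t" + "\t".join(map(str, geno.dosages[i])) + "\n")


def write_phenotypes(geno: GenotypeData, path) -> None:
    if geno.phenotypes is None:
        raise DataError("no phenotypes to write")
    pd.DataFrame({"sample_id": geno.sample_ids, "y": geno.phenotypes}).to_csv(
        path, sep="\t", index=False
    )


def _read_genotypes_tsv(path, pheno_path=None) -> GenotypeData:
    ref = alt = None
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, *vals = line.rstrip("\n").split("\t")
            if key == "#ref_alleles":
                ref = np.asarray(vals, dtype=object)
            elif key == "#alt_alleles":
                alt = np.asarray(vals, dtype=object)
            line = fh.readline()
        header = line.rstrip("\n").split("\t")
        snp_ids = header[1:]
        sample_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sample_ids.append(parts[0])
            rows.append(parts[1:])
    dos = np.asarray(rows, dtype=np.int8)
    if ref is None:
        raise DataError(f"{path}: missing #ref_alleles metadata line")
    pheno = None
    if pheno_path is not None:
        ph = pd.read_csv(pheno_path, sep="\t", dtype={"sample_id": str})
        ph = ph.set_index("sample_id").loc[[str(s) for s in sample_ids]]
        pheno = ph["y"].to_numpy(dtype=int)
    return GenotypeData(sample_ids=sample_ids, snp_ids=snp_ids,
                        ref_alleles=ref, alt_alleles=alt,
                        dosages=dos, phenotypes=pheno)


_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))  # v1.00, SNP-major
# two-bit codes -> dosage of the bim A1 allele
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_plink(prefix) -> GenotypeData:
    prefix = str(prefix)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"snp_id": str, "a1": str, "a2": str})
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise DataError(f"{prefix}.bed: not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    stride = (n + 3) // 4
    if raw.size != stride * m:
        raise DataError(
            f"{prefix}.bed: {raw.size} data bytes inconsistent with "
            f"{n} samples x {m} SNPs from fam/bim"
        )
    raw = raw.reshape(m, stride)
    # expand each byte into four 2-bit codes, sample-within-byte order LSB first
    codes = np.empty((m, stride * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    dosages = _BED_DECODE[codes[:, :n]].T  # -> samples x SNPs
    pheno = None
    ph = fam["pheno"].to_numpy()
    if np.isin(ph, (1, 2)).all():
        pheno = (ph == 2).astype(int)
    return GenotypeData(
        sample_ids=fam["iid"].tolist(),
        snp_ids=bim["snp_id"].tolist(),
        ref_alleles=bim["a1"].to_numpy(object),
        alt_alleles=bim["a2"].to_numpy(object),
        dosages=dosages,
        phenotypes=pheno,
    )


def write_plink(geno: GenotypeData, prefix) -> None:
    """Write bed/bim/fam; dosages are counted toward the bim A1 allele."""
    prefix = str(prefix)
    n, m = geno.n_samples, geno.n_snps
    alt = (geno.alt_alleles if geno.alt_alleles is not None
           else np.full(m, "N", dtype=object))
    with open(f"{prefix}.bim", "w") as fh:
        for j in range(m):
            fh.write(f"1\t{geno.snp_ids[j]}\t0\t{j + 1}\t"
                     f"{geno.ref_alleles[j]}\t{alt[j]}\n")
    with open(f"{prefix}.fam", "w") as fh:
        for i, sid in enumerate(geno.sample_ids):
            ph = -9 if geno.phenotypes is None else int(geno.phenotypes[i]) + 1
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{ph}\n")
    stride = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)
    for dos, code in _BED_ENCODE.items():
        lut[dos & 0xFF] = code
    codes = lut[geno.dosages.astype(np.int8).view(np.uint8)].T  # SNPs x samples
    padded = np.zeros((m, stride * 4), dtype=np.uint8)
    padded[:, :n] = codes
    out = np.zeros((m, stride), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_genotypes(path, format: str = "tsv", pheno_path=None) -> GenotypeData:
    """Read genotypes from a samples x SNPs TSV or a PLINK bed/bim/fam set.

    For ``plink-bed``, ``path`` is the file-set prefix (or the ``.bed`` path)
    and fam phenotype codes {1, 2} are mapped to {0, 1}.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path, pheno_path=pheno_path)
    if format == "plink-bed":
        prefix = str(path)
        if prefix.endswith(".bed"):
            prefix = prefix[:-4]
        return _read_plink(prefix)
    raise DataError(f"unknown genotype format: {format!r}")
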