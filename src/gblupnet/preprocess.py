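"""Genotype quality control and phenotype pre-correction.

QC keeps SNPs with minor allele frequency above the threshold, Hardy-Weinberg
exact-test p-value at or above the threshold, and drops markers on labeled sex
chromosomes.  Phenotype pre-correction residualizes the trait for fixed
month-of-birth (MB), herd-year (HYB), parity (PD) and compartment (HC)
effects and random pen (PE) and litter (LI) effects fitted by REML; the
residuals, z-score normalized, are the phenotype used by all downstream
genomic models.

Threshold directions: a marker is kept when MAF > ``maf_min`` and when the
HWE exact p-value is >= ``hwe_p_min``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

FIXED_FACTORS = ("MB", "HYB", "PD", "HC")
RANDOM_FACTORS = ("PE", "LI")


@dataclass
class QCReport:
    """Per-rule marker removal counts from :func:`apply_qc`."""

    n_markers_in: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_sexchr: int
    n_markers_out: int

    @property
    def retention_pct(self) -> int:
        return round(100 * self.n_markers_out / self.n_markers_in)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["retention_pct"] = self.retention_pct
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def hwe_exact_p(genotype_counts: tuple[int, int, int]) -> float:
    """Two-sided exact Hardy-Weinberg test on the heterozygote count.

    Given observed genotype counts (n_AA, n_Aa, n_aa), sums the probabilities
    of all heterozygote counts (conditional on the allele counts) that are no
    more probable than the observed one — the standard exact HWE test of
    genotype-QC tools, without a mid-p correction.
    """
    n_hom1, n_het, n_hom2 = (int(c) for c in genotype_counts)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_a = 2 * n_hom1 + n_het  # copies of the rarer-or-not allele A
    n_b = 2 * n_hom2 + n_het
    n_minor = min(n_a, n_b)

    # P(het = h | allele counts) ∝ n! / (nAA! nAa! naa!) * 2^h
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:  # inconsistent parity cannot occur with valid counts
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, probs[probs <= obs[0] * (1 + 1e-12)].sum()))


def apply_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-25,
    drop_sex_chromosomes: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the three marker-level QC rules and report per-rule counts.

    Markers failing several rules are counted once per rule but de-duplicated
    in the retained-marker arithmetic.  Raises if no marker survives.
    """
    X = genotypes.dosages
    n = X.shape[0]
    p = X.sum(axis=0) / (2 * n)
    maf = np.minimum(p, 1 - p)
    fail_maf = maf <= maf_min

    n_het = (X == 1).sum(axis=0)
    n_hom1 = (X == 0).sum(axis=0)
    n_hom2 = (X == 2).sum(axis=0)
    hwe_p = np.array(
        [hwe_exact_p((int(a), int(h), int(b))) for a, h, b in zip(n_hom1, n_het, n_hom2)]
    )
    fail_hwe = hwe_p < hwe_p_min

    fail_sex = genotypes.is_sex_chromosome() if drop_sex_chromosomes else np.zeros(len(p), bool)

    keep = ~(fail_maf | fail_hwe | fail_sex)
    if not keep.any():
        raise ValueError("QC removed every marker; check thresholds and input coding")
    report = QCReport(
        n_markers_in=genotypes.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_removed_sexchr=int(fail_sex.sum()),
        n_markers_out=int(keep.sum()),
    )
    return genotypes.subset_markers(keep), report


@dataclass
class PrecorrectionFit:
    """Mixed-model pre-correction of the raw trait.

    ``residuals`` (phenotype minus fixed-effect fit minus pen/litter BLUPs)
    are the pre-corrected phenotype.
    """

    fixed_effects: pd.Series
    pen_variance: float
    litter_variance: float
    residual_variance: float
    residuals: pd.Series
    converged: bool
    reml: "object" = None  # full VarianceComponents fit (SEs, loglik)


def _design_fixed(table: pd.DataFrame, factors=FIXED_FACTORS):
    """Full-rank treatment-coded design with intercept; drops constant/duplicate columns."""
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for f in factors:
        levels = pd.Categorical(table[f].astype(str))
        dummies = pd.get_dummies(levels, prefix=f, drop_first=True).to_numpy(float)
        for j, name in enumerate(
            pd.get_dummies(levels, prefix=f, drop_first=True).columns
        ):
            cols.append(dummies[:, j])
            names.append(name)
    X = np.column_stack(cols)
    # drop columns that are constant or linearly dependent on earlier ones
    keep, seen = [], []
    for j in range(X.shape[1]):
        v = X[:, j]
        if j > 0 and v.std() == 0:
            warnings.warn(f"dropping constant design column {names[j]}")
            continue
        trial = seen + [v]
        if np.linalg.matrix_rank(np.column_stack(trial)) == len(trial):
            keep.append(j)
            seen.append(v)
        else:
            warnings.warn(f"dropping confounded design column {names[j]}")
    return X[:, keep], [names[j] for j in keep]


def precorrect(phenotypes: pd.DataFrame, trait: str = "phenotype") -> PrecorrectionFit:
    """Residualize the trait for environmental effects with a mixed model.

    Fixed effects: MB, HYB, PD, HC (treatment-coded with intercept).  Random
    effects: pen (PE) and litter (LI), fitted by REML with an identity-block
    covariance per factor through the same average-information solver used for
    the genomic models.  Pre-corrected phenotype = residual after removing the
    fixed-effect fit and both BLUPs.
    """
    from .greml import fit_reml  # local import: greml depends only on numpy/scipy

    missing = [c for c in FIXED_FACTORS + RANDOM_FACTORS if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table lacks factor columns: {missing}")
    y = phenotypes[trait].to_numpy(float)
    X, names = _design_fixed(phenotypes)

    Zs = {}
    for f in RANDOM_FACTORS:
        Z = pd.get_dummies(phenotypes[f].astype(str)).to_numpy(float)
        Zs[f] = Z
    kernels = [("pen", Zs["PE"] @ Zs["PE"].T), ("litter", Zs["LI"] @ Zs["LI"].T)]

    fit = fit_reml(y, kernels, X=X)
    s2 = {name: fit.components[name].estimate for name in ("pen", "litter")}
    s2e = fit.sigma2_eps

    n = len(y)
    V = s2e * np.eye(n) + s2["pen"] * kernels[0][1] + s2["litter"] * kernels[1][1]
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    beta = np.linalg.solve(XtVinv @ X, XtVinv @ y)
    resid_fixed = y - X @ beta
    u_pen = s2["pen"] * Zs["PE"].T @ (Vinv @ resid_fixed)
    u_lit = s2["litter"] * Zs["LI"].T @ (Vinv @ resid_fixed)
    residuals = resid_fixed - Zs["PE"] @ u_pen - Zs["LI"] @ u_lit

    return PrecorrectionFit(
        fixed_effects=pd.Series(beta, index=names),
        pen_variance=float(s2["pen"]),
        litter_variance=float(s2["litter"]),
        residual_variance=float(s2e),
        residuals=pd.Series(residuals, index=phenotypes.index),
        converged=fit.converged,
        reml=fit,
    )


def znormalize(values) -> np.ndarray:
    """z-score normalize to mean 0 and sample SD 1 (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("z-normalization requires at least two distinct values")
    return (v - v.mean()) / v.std(ddof=1)


def read_plink_raw(path: str) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    """Read a PLINK additive-recode (.raw) text table.

    Returns (dosages, individual ids, marker ids, phenotype column).  Marker
    names follow the '<id>_<allele>' header convention; missing dosages are
    rejected because the pipeline assumes imputed input.
    """
    df = pd.read_csv(path, sep=r"\s+")
    required = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != required:
        raise ValueError("not a PLINK .raw file: first six columns must be " + " ".join(required))
    geno = df.iloc[:, 6:]
    if geno.isna().any().any():
        raise ValueError("missing genotypes are not supported; impute upstream")
    marker_ids = [c.rsplit("_", 1)[0] for c in geno.columns]
    return (
        geno.to_numpy(np.int8),
        [str(v) for v in df["IID"]],
        marker_ids,
        df["PHENOTYPE"].to_numpy(float),
    )


def read_dataset(prefix: str, format: str = "csv") -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a dataset written by :func:`gblupnet.write_dataset` (either dialect)."""
    prefix = str(prefix)
    snpinfo = pd.read_csv(prefix + ".snpinfo.csv")
    phenotypes = pd.read_csv(prefix + ".pheno.csv", index_col="IID")
    if format == "plink_raw":
        dosages, iids, marker_ids, _ = read_plink_raw(prefix + ".raw")
    elif format == "csv":
        g = pd.read_csv(prefix + ".geno.csv", index_col="IID")
        if g.isna().any().any():
            raise ValueError("missing genotypes are not supported; impute upstream")
        dosages = g.to_numpy(np.int8)
        iids = [str(v) for v in g.index]
        marker_ids = list(g.columns)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if marker_ids != list(snpinfo["marker_id"].astype(str)):
        raise ValueError("marker ids in genotype table and snpinfo sidecar disagree")
    phenotypes.index = phenotypes.index.astype(str)
    genotypes = GenotypeMatrix(
        dosages=dosages,
        marker_ids=marker_ids,
        chromosomes=snpinfo["chromosome"].astype(str).to_numpy(dtype=object),
        individual_ids=iids,
        individuals=phenotypes.loc[iids, [c for c in ("birth_year", "line") if c in phenotypes]],
    )
    return genotypes, phenotypes.loc[iids]
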