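"""Simulation of boar-like genotype/phenotype data with known genetic architecture.

Genotypes are diploid 0/1/2 dosages with a first-order Markov linkage model
along each chromosome.  Phenotypes follow the environmental structure typical
of station-tested boars — fixed month-of-birth, herd-year, parity and
compartment effects plus random pen and litter effects — on top of additive,
dominance and pairwise additive-by-additive epistatic genetic values whose
realized variance shares are rescaled to hit the requested h2/d2/e2 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

FACTOR_COLUMNS = ("MB", "HYB", "PD", "HC", "PE", "LI")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population.

    Defaults emulate the study conditions: a moderately heritable trait
    (h2 = 0.25, d2 = 0.02, e2 = 0) on z-score scale, pens of roughly ten
    animals and litters of two, and the last two birth years held out as the
    test generation.
    """

    n_individuals: int = 2000
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.5
    target_h2: float = 0.25
    target_d2: float = 0.02
    target_e2: float = 0.0
    n_pens: int | None = None       # default: one pen per ~10 animals
    n_litters: int | None = None    # default: one litter per ~2 animals
    pen_var: float = 0.3
    litter_var: float = 0.2
    factor_effect_sd: float = 0.2
    n_birth_years: int = 13
    first_birth_year: int = 2011
    test_years: tuple[int, ...] | None = None  # default: last two years
    n_epistatic_pairs: int = 100
    n_chromosomes: int = 18
    include_sex_chromosome: bool = False
    line: str = "sire"
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0 or self.n_markers <= 0:
            raise ValueError("n_individuals and n_markers must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must be in [0, 1)")
        for t in (self.target_h2, self.target_d2, self.target_e2):
            if not (0.0 <= t < 1.0):
                raise ValueError("variance-ratio targets must be in [0, 1)")
        if self.target_h2 + self.target_d2 + self.target_e2 >= 1.0:
            raise ValueError("target_h2 + target_d2 + target_e2 must be < 1")
        if self.n_pens is None:
            self.n_pens = max(1, self.n_individuals // 10)
        if self.n_litters is None:
            self.n_litters = max(1, self.n_individuals // 2)
        if self.n_pens <= 0 or self.n_litters <= 0 or self.n_birth_years <= 0:
            raise ValueError("counts must be positive")
        if self.test_years is None:
            last = self.first_birth_year + self.n_birth_years - 1
            self.test_years = (last - 1, last) if self.n_birth_years >= 3 else (last,)


@dataclass
class TruthSet:
    """Generative ground truth underlying a simulated phenotype.

    ``additive_effects`` are the exact per-marker effects of the realized
    additive values; ``dominance_effects`` and ``epistatic_pairs`` are the
    generative effects before the small orthogonalization applied so that
    component variances add exactly.  Realized ratios are shares of the
    pre-correctable (genetic + residual) phenotypic variance.
    """

    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    epistatic_pairs: list[tuple[int, int, float]]
    realized_h2: float
    realized_d2: float
    realized_e2: float
    genetic_values: pd.DataFrame = field(repr=False)  # additive/dominance/epistatic/residual columns

    @property
    def total_genetic(self) -> np.ndarray:
        g = self.genetic_values
        return (g["additive"] + g["dominance"] + g["epistatic"]).to_numpy()


def _chromosome_blocks(config: SimulationConfig) -> np.ndarray:
    n_chr = config.n_chromosomes + (1 if config.include_sex_chromosome else 0)
    labels = [str(c + 1) for c in range(config.n_chromosomes)]
    if config.include_sex_chromosome:
        labels.append("X")
    assignment = np.array(labels, dtype=object)[
        np.minimum(np.arange(config.n_markers) * n_chr // config.n_markers, n_chr - 1)
    ]
    return assignment


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw 0/1/2 genotypes with Markov linkage along each chromosome.

    Each of the two haplotypes copies its allele from the previous marker
    with probability ``ld_decay`` and otherwise draws a fresh Bernoulli(p_k)
    allele; chromosome starts always draw fresh.  With equal frequencies at
    adjacent markers this yields an adjacent-marker dosage correlation of
    approximately ``ld_decay``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    chroms = _chromosome_blocks(config)

    haplos = np.empty((n, 2, m), dtype=np.int8)
    for k in range(m):
        fresh = rng.random((n, 2)) < freqs[k]
        if k == 0 or chroms[k] != chroms[k - 1]:
            haplos[:, :, k] = fresh
        else:
            copy = rng.random((n, 2)) < config.ld_decay
            haplos[:, :, k] = np.where(copy, haplos[:, :, k - 1], fresh)
    dosages = haplos.sum(axis=1).astype(np.int8)

    years = rng.integers(0, config.n_birth_years, size=n) + config.first_birth_year
    individuals = pd.DataFrame(
        {
            "birth_year": years,
            "line": config.line,
        },
        index=[f"{config.line}_{i + 1}" for i in range(n)],
    )
    return GenotypeMatrix(
        dosages=dosages,
        marker_ids=[f"snp{k + 1}" for k in range(m)],
        chromosomes=chroms,
        individual_ids=list(individuals.index),
        individuals=individuals,
    )


def _orthogonalize(parts: list[np.ndarray]) -> list[np.ndarray]:
    """Center and Gram-Schmidt successive components so variances add exactly."""
    out = []
    for v in parts:
        v = v - v.mean()
        for u in out:
            denom = u @ u
            if denom > 0:
                v = v - (u @ v) / denom * u
        out.append(v)
    return out


def _rescale(v: np.ndarray, target_var: float) -> np.ndarray:
    sd = v.std(ddof=1)
    if target_var == 0.0 or sd == 0.0:
        return np.zeros_like(v)
    return v * np.sqrt(target_var) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate the trait plus its environmental factor table.

    Returns a phenotype table with columns ``phenotype``, ``birth_year`` and
    the factor columns MB (birth month), HYB (herd-year of birth), PD (parity
    of dam), HC (herd compartment), PE (pen) and LI (litter), together with
    the :class:`TruthSet` of generative effects and realized components.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    X = genotypes.dosages.astype(float)
    n, m = X.shape

    # generative effects; dominance effects are weighted per marker so that the
    # dominance covariance is proportional to the heterozygosity-coded D matrix
    a = rng.normal(size=m)
    p_freq = X.mean(axis=0) / 2.0
    pq = np.clip(p_freq * (1.0 - p_freq), 1e-4, None)
    d = rng.normal(size=m) / (pq * np.sqrt(2.0))
    n_pairs = min(config.n_epistatic_pairs, m * (m - 1) // 2)
    pair_idx = set()
    while len(pair_idx) < n_pairs:
        i, j = rng.integers(0, m, size=2)
        if i != j:
            pair_idx.add((min(i, j), max(i, j)))
    pair_effects = rng.normal(size=n_pairs)
    pairs = [(i, j, w) for (i, j), w in zip(sorted(pair_idx), pair_effects)]

    Xc = X - X.mean(axis=0)
    het = (X == 1).astype(float)
    g_add = Xc @ a
    g_dom = (het - het.mean(axis=0)) @ d
    g_epi = np.zeros(n)
    for i, j, w in pairs:
        g_epi += Xc[:, i] * Xc[:, j] * w
    resid = rng.normal(size=n)

    raw_dom_sd = g_dom.std(ddof=1)
    g_add, g_dom, g_epi, resid = _orthogonalize([g_add, g_dom, g_epi, resid])
    # unit pre-correctable phenotypic variance split per the targets
    target_res = 1.0 - config.target_h2 - config.target_d2 - config.target_e2
    scale_a = (
        np.sqrt(config.target_h2) / g_add.std(ddof=1)
        if config.target_h2 > 0 and g_add.std(ddof=1) > 0
        else 0.0
    )
    g_add = g_add * scale_a
    g_dom = _rescale(g_dom, config.target_d2)
    g_epi = _rescale(g_epi, config.target_e2)
    resid = _rescale(resid, target_res)
    a_scaled = a * scale_a

    # environmental structure
    pens = rng.integers(0, config.n_pens, size=n)
    litters = rng.integers(0, config.n_litters, size=n)
    months = rng.integers(1, 13, size=n)
    herd = rng.integers(0, 2, size=n)
    years = genotypes.individuals["birth_year"].to_numpy()
    herd_year = np.array([f"h{h}_{y}" for h, y in zip(herd, years)], dtype=object)
    parity = rng.integers(1, 6, size=n)
    compartment = rng.integers(0, 8, size=n)

    pen_effects = rng.normal(scale=np.sqrt(config.pen_var), size=config.n_pens)
    litter_effects = rng.normal(scale=np.sqrt(config.litter_var), size=config.n_litters)

    def level_effects(levels):
        uniq = pd.unique(levels)
        eff = dict(zip(uniq, rng.normal(scale=config.factor_effect_sd, size=len(uniq))))
        return np.array([eff[v] for v in levels])

    env = (
        pen_effects[pens]
        + litter_effects[litters]
        + level_effects(months)
        + level_effects(herd_year)
        + level_effects(parity)
        + level_effects(compartment)
    )

    y = g_add + g_dom + g_epi + resid + env

    pre_var = np.var(g_add + g_dom + g_epi + resid, ddof=1)
    truth = TruthSet(
        additive_effects=a_scaled,
        dominance_effects=d
        * (np.sqrt(config.target_d2) / raw_dom_sd if config.target_d2 > 0 and raw_dom_sd > 0 else 0.0),
        epistatic_pairs=pairs,
        realized_h2=np.var(g_add, ddof=1) / pre_var,
        realized_d2=np.var(g_dom, ddof=1) / pre_var,
        realized_e2=np.var(g_epi, ddof=1) / pre_var,
        genetic_values=pd.DataFrame(
            {
                "additive": g_add,
                "dominance": g_dom,
                "epistatic": g_epi,
                "residual": resid,
            },
            index=genotypes.individual_ids,
        ),
    )

    phenotypes = pd.DataFrame(
        {
            "phenotype": y,
            "birth_year": years,
            "MB": months,
            "HYB": herd_year,
            "PD": parity,
            "HC": compartment,
            "PE": pens,
            "LI": litters,
        },
        index=genotypes.individual_ids,
    )
    return phenotypes, truth


def write_dataset(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    prefix: str,
    format: str = "csv",
) -> list[str]:
    """Write a dataset as PLINK additive-recode text ('plink_raw') or CSV.

    Both dialects round-trip losslessly through :func:`gblupnet.read_dataset`.
    A ``<prefix>.snpinfo.csv`` sidecar carries chromosome labels (the PLINK
    .raw dialect itself has no chromosome column) and ``<prefix>.pheno.csv``
    the phenotype/factor table.
    """
    prefix = str(prefix)
    written = []
    if format == "plink_raw":
        path = prefix + ".raw"
        header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
            f"{mid}_A" for mid in genotypes.marker_ids
        ]
        with open(path, "w") as fh:
            fh.write(" ".join(header) + "\n")
            phen = phenotypes["phenotype"].to_numpy()
            for i, iid in enumerate(genotypes.individual_ids):
                row = ["0", str(iid), "0", "0", "0", repr(float(phen[i]))]
                row += [str(int(v)) for v in genotypes.dosages[i]]
                fh.write(" ".join(row) + "\n")
        written.append(path)
    elif format == "csv":
        path = prefix + ".geno.csv"
        pd.DataFrame(
            genotypes.dosages, index=genotypes.individual_ids, columns=genotypes.marker_ids
        ).to_csv(path, index_label="IID")
        written.append(path)
    else:
        raise ValueError(f"unknown format: {format!r} (expected 'plink_raw' or 'csv')")

    snpinfo = prefix + ".snpinfo.csv"
    pd.DataFrame(
        {"marker_id": genotypes.marker_ids, "chromosome": genotypes.chromosomes}
    ).to_csv(snpinfo, index=False)
    written.append(snpinfo)

    pheno_path = prefix + ".pheno.csv"
    phenotypes.to_csv(pheno_path, index_label="IID")
    written.append(pheno_path)
    return written
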