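import numpy as np
import pytest

import gblupnet as gn


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated population with environmental structure, QC'd."""
    cfg = gn.SimulationConfig(
        n_individuals=500, n_markers=300, target_h2=0.25, target_d2=0.05, seed=11
    )
    genotypes = gn.simulate_genotypes(cfg)
    phenotypes, truth = gn.simulate_phenotypes(genotypes, cfg)
    genotypes_qc, report = gn.apply_qc(genotypes)
    return dict(
        config=cfg,
        genotypes=genotypes,
        genotypes_qc=genotypes_qc,
        qc_report=report,
        phenotypes=phenotypes,
        truth=truth,
    )


@pytest.fixture(scope="session")
def clean_trait():
    """Environment-free simulation for clean genetic-parameter checks."""
    cfg = gn.SimulationConfig(
        n_individuals=800,
        n_markers=1000,
        target_h2=0.25,
        target_d2=0.0,
        target_e2=0.0,
        pen_var=0.0,
        litter_var=0.0,
        factor_effect_sd=0.0,
        seed=21,
    )
    genotypes = gn.simulate_genotypes(cfg)
    phenotypes, truth = gn.simulate_phenotypes(genotypes, cfg)
    y = gn.znormalize(phenotypes["phenotype"])
    genotypes_qc, _ = gn.apply_qc(genotypes)
    return dict(config=cfg, genotypes=genotypes_qc, phenotypes=phenotypes, truth=truth, y=y)


def hwe_genotypes(rng, n, m, maf_low=0.1, maf_high=0.5):
    """Independent HWE genotypes (binomial dosages), no linkage."""
    p = rng.uniform(maf_low, maf_high, size=m)
    return ((rng.random((n, m)) < p).astype(int) + (rng.random((n, m)) < p).astype(int)), p
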