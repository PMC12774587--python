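"""QC rules, the exact HWE test against a brute-force enumeration oracle,
mixed-model pre-correction, and z-normalization."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import gblupnet as gn
from gblupnet.genotypes import GenotypeMatrix
from gblupnet.preprocess import QCReport, _design_fixed


def hwe_exact_oracle(n_hom1, n_het, n_hom2):
    """Exact-rational enumeration of the two-sided HWE test probability."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n - n_a)

    def weight(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return Fraction(2**h * math.factorial(n), math.factorial(hom_min) * math.factorial(h) * math.factorial(hom_maj))

    hets = range(n_minor % 2, n_minor + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (10, 5, 1), (3, 3, 3), (0, 7, 5), (40, 10, 0), (1, 1, 1), (12, 0, 3)],
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert gn.hwe_exact_p(counts) == pytest.approx(hwe_exact_oracle(*counts), abs=1e-10)


def test_hwe_modal_heterozygote_count_not_significant():
    # balanced (25, 50, 25) is the modal configuration: p must be large
    assert gn.hwe_exact_p((25, 50, 25)) >= 0.5


def test_hwe_extreme_disequilibrium_is_removed():
    assert gn.hwe_exact_p((50, 0, 50)) < 1e-25


def test_hwe_monomorphic_marker_is_certain():
    assert gn.hwe_exact_p((100, 0, 0)) == 1.0
    with pytest.raises(ValueError):
        gn.hwe_exact_p((0, 0, 0))


def _column_from_counts(n0, n1, n2):
    return np.array([0] * n0 + [1] * n1 + [2] * n2)


def test_qc_maf_threshold_on_toy_markers():
    # sample MAFs 0.0, 0.04, 0.06, 0.5; only the last two survive MAF > 0.05
    cols = [
        _column_from_counts(50, 0, 0),
        _column_from_counts(46, 4, 0),
        _column_from_counts(44, 6, 0),
        _column_from_counts(13, 25, 12),
    ]
    g = GenotypeMatrix(np.column_stack(cols))
    kept, report = gn.apply_qc(g)
    assert kept.marker_ids == ["snp3", "snp4"]
    assert report.n_removed_maf == 2


def test_qc_drops_sex_chromosome_markers():
    rng = np.random.default_rng(0)
    X = (rng.random((200, 6)) < 0.4).astype(int) + (rng.random((200, 6)) < 0.4).astype(int)
    g = GenotypeMatrix(X, chromosomes=np.array(["1", "1", "X", "2", "Y", "3"], dtype=object))
    kept, report = gn.apply_qc(g)
    assert report.n_removed_sexchr == 2
    assert "X" not in kept.chromosomes and "Y" not in kept.chromosomes
    kept_all, report2 = gn.apply_qc(g, drop_sex_chromosomes=False)
    assert report2.n_removed_sexchr == 0


def test_qc_retention_percentages_from_marker_counts():
    # 36,313 of 49,478 -> 73%; 35,977 of 48,617 -> 74%
    assert QCReport(49478, 0, 0, 0, 36313).retention_pct == 73
    assert QCReport(48617, 0, 0, 0, 35977).retention_pct == 74


def test_qc_order_independence(small_dataset):
    """Applying the three rules one at a time, in any order, keeps the same set."""
    g = small_dataset["genotypes"]
    joint, _ = gn.apply_qc(g)
    rules = {
        "maf": dict(maf_min=0.05, hwe_p_min=0.0, drop_sex_chromosomes=False),
        "hwe": dict(maf_min=0.0, hwe_p_min=1e-25, drop_sex_chromosomes=False),
        "sex": dict(maf_min=0.0, hwe_p_min=0.0, drop_sex_chromosomes=True),
    }
    for order in itertools.permutations(rules):
        current = g
        for rule in order:
            current, _ = gn.apply_qc(current, **rules[rule])
        assert current.marker_ids == joint.marker_ids


def test_qc_empty_result_raises():
    g = GenotypeMatrix(_column_from_counts(50, 0, 0).reshape(-1, 1))
    with pytest.raises(ValueError, match="every marker"):
        gn.apply_qc(g)


def _single_level_table(n, rng):
    return pd.DataFrame(
        {
            "phenotype": rng.normal(size=n),
            "MB": 1,
            "HYB": "h0",
            "PD": 1,
            "HC": 0,
            "PE": 0,
            "LI": 0,
        }
    )


def test_precorrect_intercept_only_model():
    rng = np.random.default_rng(0)
    table = _single_level_table(300, rng)
    fit = gn.precorrect(table)
    y = table["phenotype"].to_numpy()
    # a single shared pen/litter is indistinguishable from the intercept, so
    # their BLUPs vanish and the residual is the centered phenotype
    assert np.allclose(fit.residuals, y - y.mean(), atol=1e-3)
    assert fit.residuals.mean() == pytest.approx(0.0, abs=1e-10)


def test_precorrect_recovers_variance_components():
    cfg = gn.SimulationConfig(
        n_individuals=1500,
        n_markers=50,
        target_h2=0.0,
        target_d2=0.0,
        pen_var=0.3,
        litter_var=0.2,
        factor_effect_sd=0.2,
        n_pens=120,
        n_litters=500,
        seed=31,
    )
    g = gn.simulate_genotypes(cfg)
    phen, _ = gn.simulate_phenotypes(g, cfg)
    fit = gn.precorrect(phen)
    pen = fit.reml.components["pen"]
    lit = fit.reml.components["litter"]
    assert abs(pen.estimate - 0.3) <= 2 * pen.se
    assert abs(lit.estimate - 0.2) <= 2 * lit.se


def test_precorrection_sharpens_genetic_signal(small_dataset):
    phen, truth = small_dataset["phenotypes"], small_dataset["truth"]
    fit = gn.precorrect(phen)
    g_true = truth.total_genetic
    r_pre = np.corrcoef(fit.residuals, g_true)[0, 1]
    r_raw = np.corrcoef(phen["phenotype"], g_true)[0, 1]
    assert r_pre > r_raw


def test_precorrect_residuals_orthogonal_to_fixed_design(small_dataset):
    phen = small_dataset["phenotypes"]
    fit = gn.precorrect(phen)
    X, _ = _design_fixed(phen)
    proj = X.T @ fit.residuals.to_numpy()
    assert np.max(np.abs(proj)) < 1e-6 * len(phen)


def test_precorrect_requires_factor_columns():
    with pytest.raises(ValueError, match="factor columns"):
        gn.precorrect(pd.DataFrame({"phenotype": [1.0, 2.0]}))


def test_znormalize_basics():
    assert np.allclose(gn.znormalize([1, 2, 3]), [-1, 0, 1])
    rng = np.random.default_rng(1)
    z = gn.znormalize(rng.normal(3.0, 2.5, size=500))
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(gn.znormalize(z), z, atol=1e-12)  # idempotence
    with pytest.raises(ValueError):
        gn.znormalize([2.0, 2.0, 2.0])
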