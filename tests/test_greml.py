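"""REML solver checks: direct likelihood evaluation, Henderson-MME oracle,
boundary behavior, and ratio arithmetic on published component values."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import gblupnet as gn
from gblupnet.greml import ComponentEstimate, VarianceComponents, fit_reml
from gblupnet.genotypes import GenotypeMatrix
from gblupnet.grm import RelationshipMatrix
from conftest import hwe_genotypes


def direct_reml_loglik(y, kernel_list, theta, X=None):
    """Dense evaluation of the restricted log-likelihood (same constant drop)."""
    n = len(y)
    X = np.ones((n, 1)) if X is None else X
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], kernel_list):
        V += t * K
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.solve(XtVinvX, X.T @ Vinv)
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVinvX)
    return -0.5 * (ld_v + ld_x + y @ P @ y)


@pytest.fixture(scope="module")
def reml_instance():
    rng = np.random.default_rng(17)
    X, _ = hwe_genotypes(rng, n=250, m=600)
    g = GenotypeMatrix(X)
    G = gn.build_G(g)
    D = gn.build_D(g)
    u = np.linalg.cholesky(G.values + 1e-6 * np.eye(250)) @ rng.normal(size=250)
    y = np.sqrt(0.3) * u / u.std() + rng.normal(scale=np.sqrt(0.7), size=250)
    return dict(y=y, G=G, D=D)


def test_loglik_matches_direct_dense_evaluation(reml_instance):
    y, G, D = reml_instance["y"], reml_instance["G"], reml_instance["D"]
    for kernels in ([("additive", G.values)], [("additive", G.values), ("dominance", D.values)]):
        fit = fit_reml(y, kernels)
        theta = np.array([c.estimate for c in fit.components.values()] + [fit.sigma2_eps])
        ll = direct_reml_loglik(y, [K for _, K in kernels], theta)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)


def test_fitted_point_is_a_local_maximum(reml_instance):
    y, G = reml_instance["y"], reml_instance["G"]
    fit = fit_reml(y, [("additive", G.values)])
    theta = np.array([fit.sigma2_a, fit.sigma2_eps])
    floor = 1e-6 * np.var(y, ddof=1)
    best = direct_reml_loglik(y, [G.values], theta)
    for i in range(2):
        if theta[i] <= floor * 1.01:
            continue  # boundary estimate: perturbation check not applicable
        for mult in (0.9, 1.1):
            pert = theta.copy()
            pert[i] *= mult
            assert direct_reml_loglik(y, [G.values], pert) <= best + 1e-6


def test_eigen_and_dense_representations_agree(reml_instance):
    from gblupnet.greml import _DenseRep, _EigenRep

    y, G = reml_instance["y"], reml_instance["G"]
    theta = np.array([0.3, 0.7])
    X = np.ones((len(y), 1))
    ll_e, sc_e, ai_e, *_ = _EigenRep(y, [("a", G.values)], X).quantities(theta)
    ll_d, sc_d, ai_d, *_ = _DenseRep(y, [("a", G.values)], X).quantities(theta)
    assert ll_e == pytest.approx(ll_d, abs=1e-8)
    assert np.allclose(sc_e, sc_d, atol=1e-8)
    assert np.allclose(ai_e, ai_d, atol=1e-8)


def test_pure_noise_gives_no_spurious_heritability():
    """Null trait: the additive variance is never significantly positive, and
    a boundary (floored) fit matches the intercept-only restricted likelihood."""
    rng = np.random.default_rng(900)  # a seed whose estimate lands on the floor
    X, _ = hwe_genotypes(rng, n=600, m=1200)
    g = GenotypeMatrix(X)
    G = gn.build_G(g)
    y = rng.normal(size=600)
    fit = fit_reml(y, [("additive", G.values)])
    floor = 1e-6 * np.var(y, ddof=1)
    assert fit.sigma2_a <= 10 * floor
    # intercept-only restricted likelihood, maximized over the residual variance
    res = minimize_scalar(
        lambda s2: -direct_reml_loglik(y, [], np.array([s2])),
        bounds=(0.1, 5.0),
        method="bounded",
    )
    assert fit.loglik == pytest.approx(-res.fun, abs=1e-3)


def test_model_tag_requirements(clean_trait):
    G = gn.build_G(clean_trait["genotypes"])
    with pytest.raises(ValueError, match="requires matrices"):
        gn.fit_model(clean_trait["y"], {"additive": G}, "AD")
    with pytest.raises(ValueError, match="unknown model"):
        gn.fit_model(clean_trait["y"], {"additive": G}, "Q")


def test_h2_recovery_single_seed(clean_trait):
    G = gn.build_G(clean_trait["genotypes"])
    fit = gn.fit_model(clean_trait["y"], {"additive": G}, "A")
    rr = gn.ratios(fit)
    assert abs(rr.h2 - clean_trait["truth"].realized_h2) <= 2.5 * rr.h2_se
    assert fit.converged


def test_ae_model_reproduces_a_model_h2(clean_trait):
    # epistasis-free trait: adding E_aa leaves the additive share unchanged
    G = gn.build_G(clean_trait["genotypes"])
    E = gn.build_Eaa(G)
    h2_a = gn.ratios(gn.fit_model(clean_trait["y"], {"additive": G}, "A")).h2
    h2_ae = gn.ratios(
        gn.fit_model(clean_trait["y"], {"additive": G, "epistatic": E}, "AE")
    ).h2
    assert abs(h2_a - h2_ae) <= 0.005


def _components_from(estimates: dict, eps, model_tag):
    k = len(estimates) + 1
    return VarianceComponents(
        components={n: ComponentEstimate(v, 0.01) for n, v in estimates.items()},
        residual=ComponentEstimate(eps, 0.01),
        model_tag=model_tag,
        loglik=0.0,
        n_iterations=1,
        converged=True,
        ai_covariance=np.eye(k) * 1e-4,
    )


def test_ratios_reproduce_published_dam_line_arithmetic():
    # AD components 0.266 / 0.023 / 0.737: h2 ~ 0.26, d2 ~ 0.022, H2 ~ 0.282
    fit = _components_from({"additive": 0.266, "dominance": 0.023}, 0.737, "AD")
    rr = gn.ratios(fit)
    assert rr.h2 == pytest.approx(0.260, abs=0.002)
    assert rr.d2 == pytest.approx(0.022, abs=0.001)
    assert rr.H2 == pytest.approx(0.282, abs=0.002)
    assert rr.H2 == pytest.approx(rr.h2 + rr.d2, abs=1e-12)
    # dominance share of total genetic variance ~ 8%
    share_genetic = 100 * 0.023 / (0.266 + 0.023)
    assert round(share_genetic) == 8
    # and 2.24% of phenotypic variance
    assert 100 * rr.d2 == pytest.approx(2.24, abs=0.01)


def test_ratio_bounds_and_total(clean_trait):
    G = gn.build_G(clean_trait["genotypes"])
    D = gn.build_D(clean_trait["genotypes"])
    fit = gn.fit_model(clean_trait["y"], {"additive": G, "dominance": D}, "AD")
    rr = gn.ratios(fit)
    assert rr.sigma2_p == pytest.approx(fit.sigma2_a + fit.sigma2_d + fit.sigma2_eps, abs=1e-10)
    for v in (rr.h2, rr.d2, rr.H2):
        assert 0.0 <= v <= 1.0


def test_predict_closed_form_single_training_animal():
    comp = _components_from({"additive": 0.4}, 0.6, "A")
    K = np.array([[1.0, 0.5], [0.5, 1.0]])
    grms = {"additive": RelationshipMatrix(K, "additive", 1)}
    y_train = np.array([1.7])
    # GLS intercept on one record equals the record itself -> EBV = 0
    ebv = gn.predict_genetic_values(comp, grms, y_train, [0], [1])
    assert ebv[0] == pytest.approx(0.0)


def test_shrinkage_limit_zero_additive_variance(clean_trait):
    G = gn.build_G(clean_trait["genotypes"])
    comp = _components_from({"additive": 1e-12}, 1.0, "A")
    ebv = gn.predict_genetic_values(
        comp, {"additive": G}, clean_trait["y"][:500], np.arange(500), np.arange(500, 600)
    )
    assert np.max(np.abs(ebv)) < 1e-9


def henderson_mme_ebv(y, G, train_idx, test_idx, s2a, s2e):
    """Mixed-model-equation solve with all animals as random-effect levels."""
    n_all = G.shape[0]
    nt = len(train_idx)
    X = np.ones((nt, 1))
    Z = np.zeros((nt, n_all))
    Z[np.arange(nt), train_idx] = 1.0
    lam = s2e / s2a
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + lam * np.linalg.inv(G)])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[1:][test_idx]


def test_predict_matches_henderson_mme():
    rng = np.random.default_rng(8)
    X, _ = hwe_genotypes(rng, n=150, m=400)
    g = GenotypeMatrix(X)
    Gk = gn.build_G(g).values + 0.05 * np.eye(150)  # keep G invertible for the MME
    grms = {"additive": RelationshipMatrix(Gk, "additive", 400)}
    y = rng.normal(size=120)
    comp = _components_from({"additive": 0.35}, 0.65, "A")
    train, test = np.arange(120), np.arange(120, 150)
    ours = gn.predict_genetic_values(comp, grms, y, train, test)
    oracle = henderson_mme_ebv(y, Gk, train, test, 0.35, 0.65)
    assert np.allclose(ours, oracle, atol=1e-8)


def test_blup_prediction_recovers_additive_values():
    cfg = gn.SimulationConfig(
        n_individuals=900, n_markers=800, target_h2=0.25, target_d2=0.0,
        pen_var=0, litter_var=0, factor_effect_sd=0, seed=41,
    )
    g = gn.simulate_genotypes(cfg)
    phen, truth = gn.simulate_phenotypes(g, cfg)
    y = gn.znormalize(phen["phenotype"])
    gq, _ = gn.apply_qc(g)
    G = gn.build_G(gq)
    train, test = np.arange(700), np.arange(700, 900)
    sub = RelationshipMatrix(G.values[np.ix_(train, train)], "additive", G.n_markers_used)
    fit = fit_reml(y[train], [("additive", sub.values)], model_tag="A")
    ebv = gn.predict_genetic_values(fit, {"additive": G}, y[train], train, test)
    truth_add = truth.genetic_values["additive"].to_numpy()[test]
    r = np.corrcoef(ebv, truth_add)[0, 1]
    assert r > 0.3  # clearly better than the zero-correlation mean baseline
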