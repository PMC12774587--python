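"""Multi-component REML (GREML) and BLUP prediction for the linear models.

The solver is average-information REML with EM-REML fallback steps and
non-negativity floors, the behavior of standard GREML tools: variance
components that iterate out of the feasible region are floored at a small
fraction of the phenotypic variance, so boundary estimates are reported with
finite standard errors from the inverse average-information matrix.

Model tags follow the additive/dominance/epistasis nesting:
A -> {G}, AD -> {G, D}, AE -> {G, E_aa}, ADE -> {G, D, E_aa}.
A single-kernel fit (the A model, and any one-matrix REML) is solved in the
eigenbasis of the kernel, where every iteration is O(n); multi-kernel fits
use the dense O(n^3) path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

MODEL_COMPONENTS = {
    "A": ("additive",),
    "AD": ("additive", "dominance"),
    "AE": ("additive", "epistatic"),
    "ADE": ("additive", "dominance", "epistatic"),
}


@dataclass
class ComponentEstimate:
    estimate: float
    se: float


@dataclass
class VarianceComponents:
    """Fitted variance components, their SEs, and fit diagnostics.

    ``components`` maps component names (in fit order) to estimates;
    ``ai_covariance`` is the inverse average-information matrix over
    (components..., residual), used for delta-method ratio SEs.
    """

    components: dict[str, ComponentEstimate]
    residual: ComponentEstimate
    model_tag: str
    loglik: float
    n_iterations: int
    converged: bool
    ai_covariance: np.ndarray = field(repr=False, default=None)

    @property
    def sigma2_eps(self) -> float:
        return self.residual.estimate

    def _get(self, name):
        return self.components[name].estimate if name in self.components else None

    @property
    def sigma2_a(self):
        return self._get("additive")

    @property
    def sigma2_d(self):
        return self._get("dominance")

    @property
    def sigma2_eaa(self):
        return self._get("epistatic")

    @property
    def sigma2_p(self) -> float:
        return sum(c.estimate for c in self.components.values()) + self.residual.estimate


class _DenseRep:
    """Dense evaluation of REML quantities for arbitrary kernel lists."""

    def __init__(self, y, kernels, X):
        self.y, self.X = y, X
        self.kernels = kernels  # list of (name, K); residual identity appended implicitly
        self.n = len(y)

    def quantities(self, theta):
        n = self.n
        V = theta[-1] * np.eye(n)
        for t, (_, K) in zip(theta[:-1], self.kernels):
            V += t * K
        try:
            c, low = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            V = V + 1e-8 * np.trace(V) / n * np.eye(n)
            c, low = linalg.cho_factor(V, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        VinvX = Vinv @ self.X
        XtVinvX = self.X.T @ VinvX
        sign, logdetX = np.linalg.slogdet(XtVinvX)
        P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
        Py = P @ self.y
        ll = -0.5 * (logdetV + logdetX + self.y @ Py)

        mats = [K for _, K in self.kernels] + [np.eye(n)]
        k = len(mats)
        trPK = np.array([np.sum(P * K) for K in mats])
        T = [K @ Py for K in mats]
        yPKPy = np.array([t @ Py for t in T])
        PT = [P @ t for t in T]
        AI = 0.5 * np.array([[T[i] @ PT[j] for j in range(k)] for i in range(k)])
        score = -0.5 * (trPK - yPKPy)
        return ll, score, AI, yPKPy, trPK


class _EigenRep:
    """Single-kernel REML in the eigenbasis of K; every iteration is O(n p^2)."""

    def __init__(self, y, kernels, X):
        (_, K), = kernels
        lam, U = np.linalg.eigh(K)
        self.lam = np.clip(lam, 0.0, None)
        self.y = U.T @ y
        self.X = U.T @ X
        self.n = len(y)

    def quantities(self, theta):
        lam, yt, Xt = self.lam, self.y, self.X
        v = theta[0] * lam + theta[1]
        vinv = 1.0 / v
        A = Xt.T @ (Xt * vinv[:, None])
        sign, logdetX = np.linalg.slogdet(A)
        beta = np.linalg.solve(A, Xt.T @ (yt * vinv))
        Py = (yt - Xt @ beta) * vinv
        ll = -0.5 * (np.sum(np.log(v)) + logdetX + yt @ Py)

        def Pw(w):
            return (w - Xt @ np.linalg.solve(A, Xt.T @ (w * vinv))) * vinv

        diags = [lam, np.ones(self.n)]
        trPK = np.array(
            [
                np.sum(d * vinv)
                - np.trace(np.linalg.solve(A, Xt.T @ (Xt * (d * vinv**2)[:, None])))
                for d in diags
            ]
        )
        T = [d * Py for d in diags]
        yPKPy = np.array([t @ Py for t in T])
        PT = [Pw(t) for t in T]
        AI = 0.5 * np.array([[T[i] @ PT[j] for j in range(2)] for i in range(2)])
        score = -0.5 * (trPK - yPKPy)
        return ll, score, AI, yPKPy, trPK


def fit_reml(
    y,
    kernels,
    X=None,
    model_tag: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    floor_frac: float = 1e-6,
) -> VarianceComponents:
    """Average-information REML with EM fallback for y = Xb + sum_i u_i + e.

    Parameters
    ----------
    y : response vector (pre-corrected, typically z-normalized phenotypes).
    kernels : list of (name, K) pairs, one n x n PSD covariance structure per
        random effect; the residual identity is implicit.
    X : fixed-effect design; defaults to an intercept column.
    model_tag : label recorded on the result (e.g. "A", "AD").
    tol : convergence threshold on the change in restricted log-likelihood.
    floor_frac : components are floored at ``floor_frac * var(y)``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    kernels = [(name, np.asarray(K, dtype=float)) for name, K in kernels]
    for name, K in kernels:
        if K.shape != (n, n):
            raise ValueError(f"kernel {name!r} does not match the number of records")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)

    rep = _EigenRep(y, kernels, X) if len(kernels) == 1 else _DenseRep(y, kernels, X)

    vary = float(np.var(y, ddof=1))
    floor = floor_frac * vary
    k = len(kernels) + 1
    theta = np.full(k, vary / k)

    ll, score, AI, yPKPy, trPK = rep.quantities(theta)
    converged = False
    it = 0
    dll = np.inf
    for it in range(1, max_iter + 1):
        # components pinned at the floor with a negative score are frozen out
        active = (theta > floor * (1 + 1e-9)) | (score > 0)
        active[-1] = True  # residual variance always free
        new_theta = new_ll = None
        try:
            delta = np.zeros(k)
            ia = np.flatnonzero(active)
            delta[ia] = np.linalg.solve(AI[np.ix_(ia, ia)], score[ia])
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            for step in (1.0, 0.5):
                cand = np.maximum(theta + step * delta, floor)
                cand_ll, *rest = rep.quantities(cand)
                if cand_ll >= ll - 1e-10:
                    new_theta, new_ll, new_rest = cand, cand_ll, rest
                    break
        if new_theta is None:
            # EM-REML fallback: theta_i <- theta_i + theta_i^2 (y'PKPy - tr(PK)) / n
            em = theta + theta**2 * (yPKPy - trPK) / n
            cand = np.where(active, np.maximum(em, floor), theta)
            cand_ll, *new_rest = rep.quantities(cand)
            new_theta, new_ll = cand, cand_ll

        dll = new_ll - ll
        theta, ll = new_theta, new_ll
        score, AI, yPKPy, trPK = new_rest
        if abs(dll) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations (|dll|={abs(dll):.2e})")

    try:
        ai_cov = np.linalg.inv(AI)
        ses = np.sqrt(np.clip(np.diag(ai_cov), 0.0, None))
    except np.linalg.LinAlgError:
        ai_cov = np.full((k, k), np.nan)
        ses = np.full(k, np.nan)

    comps = {
        name: ComponentEstimate(float(theta[i]), float(ses[i]))
        for i, (name, _) in enumerate(kernels)
    }
    return VarianceComponents(
        components=comps,
        residual=ComponentEstimate(float(theta[-1]), float(ses[-1])),
        model_tag=model_tag or "+".join(name for name, _ in kernels),
        loglik=float(ll),
        n_iterations=it,
        converged=converged,
        ai_covariance=ai_cov,
    )


def fit_model(y, grms: dict, model_tag: str, **kwargs) -> VarianceComponents:
    """Fit one of the A/AD/AE/ADE models from a dict of RelationshipMatrix."""
    if model_tag not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model tag {model_tag!r}")
    names = MODEL_COMPONENTS[model_tag]
    missing = [nm for nm in names if nm not in grms]
    if missing:
        raise ValueError(f"model {model_tag} requires matrices: {missing}")
    kernels = [(nm, grms[nm].values) for nm in names]
    return fit_reml(y, kernels, model_tag=model_tag, **kwargs)


@dataclass
class HeritabilityRatios:
    """Variance-component ratios with delta-method SEs.

    h2 = additive share, d2 = dominance share, e2_aa = epistatic share of the
    phenotypic variance (the sum of all fitted components); H2 is the sum of
    the genetic shares present in the model.
    """

    sigma2_p: float
    h2: float
    h2_se: float
    d2: float | None = None
    d2_se: float | None = None
    e2_aa: float | None = None
    e2_aa_se: float | None = None
    H2: float | None = None
    H2_se: float | None = None


def _ratio_se(weights: np.ndarray, theta: np.ndarray, cov: np.ndarray) -> float:
    """Delta-method SE of (w . theta) / (1 . theta)."""
    S = theta.sum()
    num = float(weights @ theta)
    grad = (weights * S - num) / S**2
    if cov is None or not np.all(np.isfinite(cov)):
        return float("nan")
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def ratios(components: VarianceComponents) -> HeritabilityRatios:
    """Compute h2/d2/e2_aa/H2 and their SEs from fitted components."""
    names = list(components.components)
    theta = np.array([components.components[nm].estimate for nm in names] + [components.sigma2_eps])
    S = theta.sum()
    if S <= 0:
        raise ValueError("total phenotypic variance is zero")
    cov = components.ai_covariance

    def one(name):
        if name not in names:
            return None, None
        w = np.array([1.0 if nm == name else 0.0 for nm in names] + [0.0])
        return float(theta[names.index(name)] / S), _ratio_se(w, theta, cov)

    h2, h2_se = one("additive")
    d2, d2_se = one("dominance")
    e2, e2_se = one("epistatic")
    w_gen = np.array([1.0] * len(names) + [0.0])
    genetic = [x for x in (h2, d2, e2) if x is not None]
    H2 = sum(genetic) if len(genetic) > 1 else None
    H2_se = _ratio_se(w_gen, theta, cov) if H2 is not None else None
    return HeritabilityRatios(
        sigma2_p=float(S),
        h2=h2,
        h2_se=h2_se,
        d2=d2,
        d2_se=d2_se,
        e2_aa=e2,
        e2_aa_se=e2_se,
        H2=H2,
        H2_se=H2_se,
    )


def predict_genetic_values(
    components: VarianceComponents,
    grms: dict,
    y_train,
    train_idx,
    test_idx,
    component: str = "additive",
) -> np.ndarray:
    """BLUP prediction of test-animal genetic values from a training fit.

    u_test = sigma2_c K_c[test, train] V_train^{-1} (y_train - mu_hat), with
    V_train built from all fitted components on the training block and mu_hat
    the GLS intercept.  By default the additive component (the EBV) is
    returned; other fitted components are predicted analogously by name.
    """
    if component not in components.components:
        raise ValueError(f"component {component!r} not in fitted model {components.model_tag}")
    y_train = np.asarray(y_train, dtype=float)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    nt = len(train_idx)
    if len(y_train) != nt:
        raise ValueError("y_train length must match train_idx")

    V = components.sigma2_eps * np.eye(nt)
    for nm, est in components.components.items():
        K = grms[nm].values
        V += est.estimate * K[np.ix_(train_idx, train_idx)]
    c, low = linalg.cho_factor(V, check_finite=False)
    ones = np.ones(nt)
    Vinv_y = linalg.cho_solve((c, low), y_train, check_finite=False)
    Vinv_1 = linalg.cho_solve((c, low), ones, check_finite=False)
    mu = float(ones @ Vinv_y) / float(ones @ Vinv_1)
    w = linalg.cho_solve((c, low), y_train - mu * ones, check_finite=False)
    K = grms[component].values
    s2 = components.components[component].estimate
    return s2 * (K[np.ix_(test_idx, train_idx)] @ w)
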