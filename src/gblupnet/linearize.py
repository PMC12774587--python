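"""Probe-matrix linearization of black-box genotype-to-phenotype models.

Any trained predictor f is probed with an (m + 1, m) matrix K whose first row
is all zeros and whose remaining rows form the identity: the additive effect
of marker k is a_k = f(e_k) - f(0).  Multiplying test genotypes by these
effects gives a linear-approximation EBV (= X a); the model's own predictions
are the EGV (= f(X)).  The share of the model's predicted genetic variance
not explained by its linear approximation is n2 = 1 - corr(EGV, EBV)^2, and
the nonadditive variance it captures is sigma2_NADL = n2 * var(EGV).

Probe genotypes are 0 and 1 (not 0 and 2), so a_k measures the 0 -> 1
(heterozygote) step of the model response at the all-zero background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _predict(model, X):
    fn = getattr(model, "predict", model)
    return np.asarray(fn(np.asarray(X, dtype=float))).reshape(-1)


@dataclass
class LinearizationResult:
    """Per-marker additive effects, EBV/EGV vectors and variance summary."""

    additive_effects: np.ndarray
    y0_hat: float
    ebv: np.ndarray
    egv: np.ndarray
    n2: float
    sigma2_u_dl: float
    sigma2_na_dl: float


def build_probe(m: int) -> np.ndarray:
    """The (m + 1, m) probe: a zero row stacked on the m x m identity."""
    if m < 1:
        raise ValueError("need at least one marker")
    return np.vstack([np.zeros((1, m)), np.eye(m)])


def extract_additive_effects(model, m: int) -> tuple[np.ndarray, float]:
    """Per-marker additive effects a_k = f(e_k) - f(0), one batched forward pass."""
    preds = _predict(model, build_probe(m))
    y0 = float(preds[0])
    return preds[1:] - y0, y0


def compute_ebv(X_test, a) -> np.ndarray:
    """Linear-approximation breeding values: EBV = X a."""
    X_test = np.asarray(X_test, dtype=float)
    a = np.asarray(a, dtype=float)
    if X_test.shape[1] != a.shape[0]:
        raise ValueError("marker count of X_test does not match effect vector")
    return X_test @ a


def compute_egv(model, X_test) -> np.ndarray:
    """Full-model genetic values: EGV = f(X_test)."""
    return _predict(model, X_test)


def nonadditive_summary(ebv, egv) -> tuple[float, float, float]:
    """(n2, sigma2_u_dl, sigma2_na_dl) from aligned EBV and EGV vectors.

    n2 = 1 - corr(EGV, EBV)^2; sigma2_u_dl is the sample variance (n - 1) of
    the EGV; sigma2_na_dl = n2 * sigma2_u_dl.
    """
    ebv = np.asarray(ebv, dtype=float)
    egv = np.asarray(egv, dtype=float)
    if ebv.shape != egv.shape or ebv.size < 3:
        raise ValueError("ebv and egv must be equal-length vectors of size >= 3")
    if ebv.std() == 0 or egv.std() == 0:
        raise ValueError("n2 undefined: constant EBV or EGV vector")
    r = float(np.corrcoef(egv, ebv)[0, 1])
    n2 = 1.0 - r**2
    s2u = float(egv.var(ddof=1))
    return n2, s2u, n2 * s2u


def linearize_model(model, X_test) -> LinearizationResult:
    """Full probe-extract-summarize pass for one trained model on one test set."""
    m = np.asarray(X_test).shape[1]
    a, y0 = extract_additive_effects(model, m)
    ebv = compute_ebv(X_test, a)
    egv = compute_egv(model, X_test)
    n2, s2u, s2na = nonadditive_summary(ebv, egv)
    return LinearizationResult(
        additive_effects=a, y0_hat=y0, ebv=ebv, egv=egv,
        n2=n2, sigma2_u_dl=s2u, sigma2_na_dl=s2na,
    )


@dataclass
class PooledLinearization:
    """Across-split aggregation of per-split linearizations."""

    n2: float
    sigma2_u_dl: float
    sigma2_na_dl: float
    avg_ebv: np.ndarray
    avg_egv: np.ndarray
    cor_avg_ebv: float | None = None
    cor_avg_egv: float | None = None


def pooled_summary(
    results: list[LinearizationResult], y_test=None, mode: str = "average"
) -> PooledLinearization:
    """Aggregate split results by per-animal averaging (default) or concatenation.

    'average' computes n2 from the per-animal mean EBV/EGV across splits;
    'concat' computes it from the concatenated per-split vectors.  When
    ``y_test`` is given, the two comparison correlations corr(avg_ebv, y_test)
    and corr(avg_egv, y_test) are reported as well.
    """
    if not results:
        raise ValueError("need at least one split result")
    n_test = results[0].ebv.shape[0]
    for r in results:
        if r.ebv.shape[0] != n_test:
            raise ValueError("split results cover different test sets")
    ebv_mat = np.vstack([r.ebv for r in results])
    egv_mat = np.vstack([r.egv for r in results])
    avg_ebv = ebv_mat.mean(axis=0)
    avg_egv = egv_mat.mean(axis=0)
    if mode == "average":
        n2, s2u, s2na = nonadditive_summary(avg_ebv, avg_egv)
    elif mode == "concat":
        n2, s2u, s2na = nonadditive_summary(ebv_mat.ravel(), egv_mat.ravel())
    else:
        raise ValueError("mode must be 'average' or 'concat'")
    cor_ebv = cor_egv = None
    if y_test is not None:
        y_test = np.asarray(y_test, dtype=float)
        cor_ebv = float(np.corrcoef(avg_ebv, y_test)[0, 1])
        cor_egv = float(np.corrcoef(avg_egv, y_test)[0, 1])
    return PooledLinearization(
        n2=n2, sigma2_u_dl=s2u, sigma2_na_dl=s2na,
        avg_ebv=avg_ebv, avg_egv=avg_egv,
        cor_avg_ebv=cor_ebv, cor_avg_egv=cor_egv,
    )
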