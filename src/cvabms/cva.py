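"""Canonical Variates Analysis with BIC-approximated Bayes factors.

CVA (equivalently, canonical correlation analysis) finds paired linear
projections ``Xa`` and ``Yb`` of a design matrix ``X`` (n x q) and a
feature matrix ``Y`` (n x d) with maximal correlation.  With
``S_xx, S_yy, S_xy`` the (maximum-likelihood, divide-by-n) sample
covariances of the centered variables, the canonical correlations
``rho_1 >= ... >= rho_s`` are the singular values of the whitened
cross-covariance ``S_xx^{-1/2} S_xy S_yy^{-1/2}``, with
``s = min(q, d, n - 1)``.

The dimension (order) of a CVA model is the number of nonzero canonical
vector pairs.  Wilk's Lambda for order ``m`` is

    Lambda_m = prod_{i<=m} (1 - rho_i^2)

and can equivalently be computed from the generalized eigenvalues
``lambda_i`` of the explained-vs-residual covariance problem
(``Lambda_m = prod_{i<=m} 1/(1 + lambda_i)``, since
``rho_i^2 = lambda_i / (1 + lambda_i)``), or from the log-likelihood
ratio ``L_m = -(n/2) log Lambda_m``.  All three routes are implemented
and agree to tight tolerance; the cross-check is part of the test suite.

Model evidence is approximated by BIC, giving the log Bayes factor of the
order-``m`` model against the null (order-0) model:

    logBF_m0 = -(n/2) sum_{i<=m} log(1 - rho_i^2) - (k_m/2) log n

where ``k_m = m (d + q - m)`` counts the parameters of a rank-m linear
dependence beyond the null (for the common q = 1, m = 1 case, ``k = d``).
Negative values favour the null.  The selected order is the argmax of
``logBF`` over ``m = 0..s``, ties going to the smaller order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import InconsistentDataError, InsufficientDataError, ShapeError, ValidationError
from .features import FeatureMatrix

__all__ = [
    "CvaResult",
    "CovPartition",
    "fit_cva",
    "partition_covariance",
    "wilks_lambda_from_correlations",
    "wilks_lambda_from_partition",
    "log_likelihood_ratio",
    "bic_log_bayes_factor",
    "log_bayes_factor",
    "default_param_count",
    "select_order",
    "compare_feature_models",
]

# Correlations this close to 1 are treated as saturated before taking logs.
_RHO_CLIP = 1.0 - 1e-12
_EIG_FLOOR_REL = 1e-10


def default_param_count(m: int, q: int, d: int) -> int:
    """Parameters of a rank-m linear dependence beyond the null: m(d+q-m)."""
    return m * (d + q - m)


@dataclass
class CvaResult:
    """Fitted CVA model with per-order evidence scores.

    ``wilks_lambda``, ``loglik_ratio``, ``log_bf`` and ``k`` are arrays of
    length ``s + 1`` indexed by model order ``m = 0..s``; order 0 is the
    null model, for which ``L_0 = 0`` and ``logBF_00 = 0`` exactly.
    """

    rho: np.ndarray
    a: np.ndarray
    b: np.ndarray
    n: int
    q: int
    d: int
    wilks_lambda: np.ndarray
    loglik_ratio: np.ndarray
    log_bf: np.ndarray
    k: np.ndarray
    selected_order: int
    saturated: bool = False

    @property
    def s(self) -> int:
        return self.rho.size

    @classmethod
    def from_correlations(
        cls,
        rho: np.ndarray,
        n: int,
        q: int,
        d: int,
        a: np.ndarray | None = None,
        b: np.ndarray | None = None,
        param_count=default_param_count,
    ) -> "CvaResult":
        """Assemble per-order scores from given canonical correlations."""
        rho = np.clip(np.asarray(rho, dtype=float).ravel(), 0.0, 1.0)
        if np.any(np.diff(rho) > 1e-10):
            raise ValidationError("canonical correlations must be non-increasing")
        s = rho.size
        orders = np.arange(s + 1)
        k = np.array([param_count(m, q, d) for m in orders], dtype=float)
        loglik = np.array([log_likelihood_ratio(rho, m, n) for m in orders])
        wilks = np.array([wilks_lambda_from_correlations(rho, m) for m in orders])
        logbf = np.array(
            [bic_log_bayes_factor(rho, n, m, k=k[m]) for m in orders]
        )
        saturated = bool(np.any(rho >= _RHO_CLIP))
        a = np.zeros((q, s)) if a is None else a
        b = np.zeros((d, s)) if b is None else b
        return cls(
            rho=rho, a=a, b=b, n=int(n), q=int(q), d=int(d),
            wilks_lambda=wilks, loglik_ratio=loglik, log_bf=logbf, k=k,
            selected_order=int(np.argmax(logbf)), saturated=saturated,
        )


@dataclass(frozen=True)
class CovPartition:
    """Explained (H) and residual (R) covariance of the features."""

    explained: np.ndarray
    residual: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.explained, dtype=float)
        r = np.asarray(self.residual, dtype=float)
        if h.shape != r.shape or h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ShapeError("H and R must be square matrices of equal shape")
        object.__setattr__(self, "explained", 0.5 * (h + h.T))
        object.__setattr__(self, "residual", 0.5 * (r + r.T))

    @property
    def total(self) -> np.ndarray:
        return self.explained + self.residual


def _as_2d(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        x = x.values
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ShapeError(f"expected a vector or matrix, got shape {x.shape}")
    return x


def _inv_sqrt_psd(S: np.ndarray, label: str = "") -> np.ndarray:
    """Symmetric inverse square root with a relative eigenvalue floor."""
    w, V = linalg.eigh(0.5 * (S + S.T))
    floor = _EIG_FLOOR_REL * max(float(np.trace(S)), np.finfo(float).tiny)
    if w[0] < floor:
        warnings.warn(
            f"rank-deficient covariance{f' ({label})' if label else ''}: "
            "eigenvalues floored",
            RuntimeWarning,
            stacklevel=3,
        )
        w = np.maximum(w, floor)
    return (V / np.sqrt(w)) @ V.T


def fit_cva(X, Y, param_count=default_param_count, label: str = "") -> CvaResult:
    """Fit CVA between design ``X`` (n x q) and features ``Y`` (n x d).

    Both matrices are mean-centered internally.  Returns canonical
    correlations, canonical vector pairs scaled so each canonical variate
    has unit (ML) variance, and per-order Wilk's Lambda, log-likelihood
    ratio and BIC log Bayes factor versus the null.
    """
    X = _as_2d(X)
    Y = _as_2d(Y)
    if X.shape[0] != Y.shape[0]:
        raise ShapeError(
            f"X has {X.shape[0]} rows but Y has {Y.shape[0]}"
        )
    n, q = X.shape
    d = Y.shape[1]
    if n <= d + q:
        raise InsufficientDataError(
            f"n={n} trials cannot support a CVA with q={q} design columns "
            f"and d={d} features (need n > d + q)"
        )
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / n
    Syy = Yc.T @ Yc / n
    Sxy = Xc.T @ Yc / n
    Wx = _inv_sqrt_psd(Sxx, label=f"design{' ' + label if label else ''}")
    Wy = _inv_sqrt_psd(Syy, label=f"features{' ' + label if label else ''}")
    U, sv, Vt = linalg.svd(Wx @ Sxy @ Wy)
    s = min(q, d, n - 1)
    rho = np.clip(sv[:s], 0.0, 1.0)
    a = Wx @ U[:, :s]
    b = Wy @ Vt.T[:, :s]
    return CvaResult.from_correlations(rho, n, q, d, a=a, b=b, param_count=param_count)


def partition_covariance(X, Y) -> CovPartition:
    """Explained/residual split of the feature covariance under design X.

    Predictions are the least-squares fit of centered Y on centered X;
    ``H`` is the ML covariance of the predictions and ``R`` of the
    residuals, so ``H + R`` equals the total feature covariance.
    """
    X = _as_2d(X)
    Y = _as_2d(Y)
    if X.shape[0] != Y.shape[0]:
        raise ShapeError("X and Y row counts differ")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    B, *_ = linalg.lstsq(Xc, Yc)
    Yhat = Xc @ B
    resid = Yc - Yhat
    return CovPartition(explained=Yhat.T @ Yhat / n, residual=resid.T @ resid / n)


def wilks_lambda_from_correlations(rho: np.ndarray, m: int) -> float:
    """Wilk's Lambda for order m: product over i<=m of (1 - rho_i^2)."""
    rho = np.asarray(rho, dtype=float).ravel()
    if m < 0 or m > rho.size:
        raise ValidationError(f"order m={m} outside 0..{rho.size}")
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValidationError("correlations must lie in [0, 1]")
    return float(np.prod(1.0 - rho[:m] ** 2))


def wilks_lambda_from_partition(part: CovPartition, m: int) -> float:
    """Wilk's Lambda via eigenvalues of the explained-vs-residual problem.

    With ``lambda_i`` the (descending) generalized eigenvalues of
    ``H v = lambda R v``, order-m Lambda is ``prod_{i<=m} 1/(1+lambda_i)``.
    A singular ``R`` is handled by flooring its eigenvalues, with a warning.
    """
    H, R = part.explained, part.residual
    if m < 0 or m > H.shape[0]:
        raise ValidationError(f"order m={m} outside 0..{H.shape[0]}")
    w, V = linalg.eigh(R)
    floor = _EIG_FLOOR_REL * max(float(np.trace(R)), np.finfo(float).tiny)
    if w[0] < floor:
        warnings.warn(
            "singular residual covariance: eigenvalues floored",
            RuntimeWarning,
            stacklevel=2,
        )
        w = np.maximum(w, floor)
    Rinv_sqrt = (V / np.sqrt(w)) @ V.T
    lam = np.sort(linalg.eigvalsh(Rinv_sqrt @ H @ Rinv_sqrt))[::-1]
    lam = np.clip(lam, 0.0, None)
    return float(np.prod(1.0 / (1.0 + lam[:m])))


def log_likelihood_ratio(rho: np.ndarray, m: int, n: int) -> float:
    """L_m = -(n/2) sum_{i<=m} log(1 - rho_i^2); the order-0 value is 0."""
    rho = np.asarray(rho, dtype=float).ravel()
    if m < 0 or m > rho.size:
        raise ValidationError(f"order m={m} outside 0..{rho.size}")
    if m == 0:
        return 0.0
    r = rho[:m]
    if np.any(r >= 1.0):
        return np.inf
    r = np.minimum(r, _RHO_CLIP)
    return float(-(n / 2.0) * np.sum(np.log1p(-(r ** 2))))


def bic_log_bayes_factor(
    rho: np.ndarray, n: int, m: int, q: int | None = None,
    d: int | None = None, k: float | None = None,
) -> float:
    """BIC log Bayes factor of the order-m model versus the null.

    ``k`` may be supplied directly; otherwise it is ``m (d + q - m)``.
    Order 0 returns exactly 0.  A correlation of exactly 1 saturates the
    likelihood, returning ``+inf``.
    """
    if m == 0:
        return 0.0
    if k is None:
        if q is None or d is None:
            raise ValidationError("supply either k or both q and d")
        k = default_param_count(m, q, d)
    L = log_likelihood_ratio(rho, m, n)
    if np.isinf(L):
        return np.inf
    return float(L - (k / 2.0) * np.log(n))


def log_bayes_factor(result: CvaResult, m: int) -> float:
    """Log Bayes factor of order ``m`` versus the null from a fitted result."""
    if m < 0 or m > result.s:
        raise ValidationError(f"order m={m} outside 0..{result.s}")
    return float(result.log_bf[m])


def select_order(result: CvaResult) -> int:
    """Order with the largest log Bayes factor; ties go to the smaller order."""
    return int(np.argmax(result.log_bf))


def compare_feature_models(
    logbf_by_model: Mapping[int, float] | pd.Series,
    n_trials_by_model: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Pairwise log Bayes factors between feature-set models.

    All entries must be log Bayes factors against the same null model
    computed on identical data; then ``logBF(i vs j) = logBF_i0 - logBF_j0``.
    Returns an antisymmetric models x models DataFrame.
    """
    series = pd.Series(dict(logbf_by_model), dtype=float)
    if n_trials_by_model is not None:
        counts = set(n_trials_by_model.values())
        if len(counts) > 1:
            raise InconsistentDataError(
                f"models were scored on different trial counts: {sorted(counts)}; "
                "Bayes factors are only comparable on identical data"
            )
    vals = series.to_numpy()
    mat = vals[:, None] - vals[None, :]
    return pd.DataFrame(mat, index=series.index, columns=series.index)
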