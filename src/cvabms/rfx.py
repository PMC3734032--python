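"""Random-effects Bayesian model selection over a group of subjects.

Treats the model that generated each subject's data as a draw from
unknown population frequencies ``r`` with a Dirichlet prior
``p(r) = Dir(alpha_0)`` (default all ones: one prior observation of each
model, a flat prior).  Given an N-subjects x K-models table of log
evidences -- or log Bayes factors against a shared reference model --
the posterior over ``r`` is approximated as ``Dir(alpha)`` by iterating

    u_nk  propto  exp( logEv_nk + psi(alpha_k) - psi(sum_j alpha_j) )
    alpha_k = alpha0_k + sum_n u_nk

where ``psi`` is the digamma function and each row of ``u`` (the posterior
probability that subject ``n`` used model ``k``) is normalized to 1.
Only within-row differences of the evidence table matter, so any shared
reference model cancels.

Summaries: the expected frequency of model ``k`` is ``alpha_k / sum alpha``;
the exceedance probability is the posterior probability that model ``k``'s
frequency is the largest (for K = 2, the Beta tail mass beyond 1/2,
computed analytically; for K > 2, a seeded Monte-Carlo estimate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp
from scipy.stats import beta as beta_dist

from .errors import ValidationError

__all__ = [
    "EvidenceTable",
    "BmsPosterior",
    "fit_rfx",
    "expected_frequencies",
    "exceedance_probabilities",
]


@dataclass
class EvidenceTable:
    """N subjects x K models table of log evidences (or common-null logBF)."""

    values: np.ndarray
    model_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError(f"evidence table must be 2-D, got shape {v.shape}")
        if v.shape[1] < 2:
            raise ValidationError("evidence table needs at least two models")
        if not np.all(np.isfinite(v)):
            raise ValidationError("evidence table contains non-finite entries")
        if self.model_names is None:
            names = tuple(f"model_{k}" for k in range(v.shape[1]))
        else:
            names = tuple(str(m) for m in self.model_names)
            if len(names) != v.shape[1]:
                raise ValidationError(
                    f"{len(names)} model names for {v.shape[1]} columns"
                )
        self.values = v
        self.model_names = names

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_models(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(cls, path) -> "EvidenceTable":
        df = pd.read_csv(path)
        return cls(values=df.to_numpy(dtype=float), model_names=tuple(df.columns))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, columns=list(self.model_names)).to_csv(
            path, index=False
        )


@dataclass
class BmsPosterior:
    """Dirichlet posterior over population model frequencies."""

    alpha0: np.ndarray
    alpha: np.ndarray
    u: np.ndarray
    model_names: tuple[str, ...]
    iterations: int
    converged: bool

    @property
    def expected_frequencies(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": list(self.model_names),
                "alpha": self.alpha,
                "expected_frequency": self.expected_frequencies,
            }
        )


def _coerce_table(table) -> EvidenceTable:
    if isinstance(table, EvidenceTable):
        return table
    if isinstance(table, pd.DataFrame):
        return EvidenceTable(
            values=table.to_numpy(dtype=float), model_names=tuple(map(str, table.columns))
        )
    return EvidenceTable(values=np.asarray(table, dtype=float))


def fit_rfx(
    table,
    alpha0: np.ndarray | float | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BmsPosterior:
    """Fit the Dirichlet posterior over model frequencies.

    Parameters
    ----------
    table:
        EvidenceTable, DataFrame, or (N, K) array of log evidences / logBF
        against a common reference.  An empty table (N = 0) returns the
        prior.
    alpha0:
        Prior counts, scalar or length-K, strictly positive.  Default 1 per
        model (flat prior).
    tol, max_iter:
        Iterate until the largest absolute change in ``alpha`` falls below
        ``tol`` or ``max_iter`` updates; non-convergence returns the last
        iterate with ``converged=False`` and a warning.
    """
    tab = _coerce_table(table)
    E = tab.values
    N, K = E.shape
    if alpha0 is None:
        a0 = np.ones(K)
    else:
        a0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    if np.any(a0 <= 0) or not np.all(np.isfinite(a0)):
        raise ValidationError("prior counts alpha0 must be finite and positive")
    if N == 0:
        return BmsPosterior(
            alpha0=a0, alpha=a0.copy(), u=np.zeros((0, K)),
            model_names=tab.model_names, iterations=0, converged=True,
        )
    alpha = a0.copy()
    u = np.full((N, K), 1.0 / K)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_u = E + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = a0 + u.sum(axis=0)
        delta = np.abs(alpha_new - alpha).max()
        alpha = alpha_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RFX-BMS did not converge in {max_iter} iterations "
            f"(last max |delta alpha| = {delta:.3g})",
            RuntimeWarning,
        )
    return BmsPosterior(
        alpha0=a0, alpha=alpha, u=u, model_names=tab.model_names,
        iterations=it, converged=converged,
    )


def expected_frequencies(post: BmsPosterior) -> np.ndarray:
    """Posterior-mean model frequencies, alpha / sum(alpha)."""
    return post.expected_frequencies


def exceedance_probabilities(
    post: BmsPosterior,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    method: str = "auto",
) -> np.ndarray:
    """Probability that each model's frequency exceeds all others'.

    K = 2 is exact: ``phi_1 = P(r_1 > 1/2)`` under ``r_1 ~ Beta(a_1, a_2)``.
    K > 2 draws ``n_samples`` Dirichlet samples with a seeded generator and
    counts how often each model's frequency is the maximum.  ``method`` may
    force ``"sampling"`` (also for K = 2, e.g. to validate the estimator)
    or ``"analytic"`` (K = 2 only).
    """
    if method not in ("auto", "analytic", "sampling"):
        raise ValidationError("method must be 'auto', 'analytic' or 'sampling'")
    alpha = post.alpha
    K = alpha.size
    if method == "analytic" and K != 2:
        raise ValidationError("analytic exceedance is only available for K = 2")
    if K == 2 and method != "sampling":
        phi1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        return np.array([phi1, 1.0 - phi1])
    if n_samples < 1:
        raise ValidationError("n_samples must be at least 1")
    if n_samples < 1000:
        warnings.warn(
            f"n_samples={n_samples} is small for a Monte-Carlo exceedance "
            "estimate; consider >= 1000",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    counts = np.zeros(K)
    remaining = int(n_samples)
    # chunked to bound memory at large sample counts
    while remaining > 0:
        chunk = min(remaining, 500_000)
        samples = rng.dirichlet(alpha, size=chunk)
        winners = np.argmax(samples, axis=1)
        counts += np.bincount(winners, minlength=K)
        remaining -= chunk
    return counts / n_samples
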