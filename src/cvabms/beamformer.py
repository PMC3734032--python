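"""LCMV beamformer projection of sensor-level Fourier coefficients.

A linearly constrained minimum variance (LCMV) beamformer passes activity
from one source location with unit gain while minimising the variance
contributed by all other locations.  Given a lead field ``L`` (the sensor
gain pattern of a unit source) and the sensor covariance ``C``, the spatial
filter for an oriented (single-column) lead field ``l`` is

    w = C^{-1} l (l^T C^{-1} l)^{-1}

so that ``w^T l = 1`` exactly.  For a free-orientation (three-column) lead
field the source orientation is chosen to maximise projected power, which
for unit-gain weights equals ``1 / (u^T L^T C^{-1} L u)``: the maximising
``u`` is the eigenvector of ``L^T C^{-1} L`` with the smallest eigenvalue.

No regularisation is applied by default; a covariance whose condition
number exceeds ``COND_LIMIT`` raises rather than being silently ridged.
An explicit ``ridge`` (added to the diagonal of ``C``) is available for
callers who want one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import (
    InvalidLeadFieldError,
    ShapeError,
    SingularCovarianceError,
    ValidationError,
)

__all__ = [
    "LeadField",
    "SensorCovariance",
    "BeamformerWeights",
    "TrialSpectra",
    "select_orientation",
    "lcmv_weights",
    "project_trials",
]

#: Covariance condition-number limit beyond which inversion is refused.
COND_LIMIT = 1e12

#: Tolerance for the unit-gain contract w^T l = 1.
UNIT_GAIN_TOL = 1e-8


@dataclass(frozen=True)
class LeadField:
    """Sensor gain pattern of a unit source at one location.

    ``matrix`` has shape (channels, 3) for a free-orientation source or
    (channels, 1) for a fixed orientation.
    """

    matrix: np.ndarray
    location_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] not in (1, 3):
            raise ShapeError(
                f"lead field must be (channels, 1) or (channels, 3), got {m.shape}"
            )
        if not np.all(np.isfinite(m)):
            raise ValidationError("lead field contains non-finite entries")
        if np.any(np.all(m == 0.0, axis=0)):
            raise InvalidLeadFieldError(
                f"lead field {self.location_id!r} has an all-zero column"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SensorCovariance:
    """Symmetric sensor-space covariance of the measured signal."""

    matrix: np.ndarray
    symmetry_tol: float = 1e-8

    def __post_init__(self) -> None:
        c = np.asarray(self.matrix, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ShapeError(f"covariance must be square, got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValidationError("covariance contains non-finite entries")
        scale = max(np.abs(c).max(), 1.0)
        if np.abs(c - c.T).max() > self.symmetry_tol * scale:
            raise ValidationError("covariance is not symmetric within tolerance")
        object.__setattr__(self, "matrix", 0.5 * (c + c.T))

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class BeamformerWeights:
    """Unit-gain spatial filter for a single source location."""

    weights: np.ndarray
    oriented_leadfield: np.ndarray
    orientation: np.ndarray | None = None
    location_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        l = np.asarray(self.oriented_leadfield, dtype=float).ravel()
        if w.shape != l.shape:
            raise ShapeError("weights and oriented lead field differ in length")
        gain = float(w @ l)
        if abs(gain - 1.0) > UNIT_GAIN_TOL:
            raise ValidationError(f"unit-gain violated: w^T l = {gain!r}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "oriented_leadfield", l)


@dataclass
class TrialSpectra:
    """Per-trial complex Fourier coefficients.

    Sensor level: ``coeffs`` has shape (trials, channels, bins).
    Source level: ``coeffs`` has shape (trials, bins).
    ``condition_labels`` holds one class label per trial (+1 post-stimulus,
    -1 pre-stimulus in the default paradigm).
    """

    coeffs: np.ndarray
    bin_frequencies: np.ndarray
    condition_labels: np.ndarray
    location_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=complex)
        f = np.asarray(self.bin_frequencies, dtype=float).ravel()
        lab = np.asarray(self.condition_labels).ravel()
        if c.ndim not in (2, 3):
            raise ShapeError(
                f"coeffs must be (trials, bins) or (trials, channels, bins), got {c.shape}"
            )
        if c.shape[-1] != f.size:
            raise ShapeError(
                f"{c.shape[-1]} frequency bins in coeffs but {f.size} bin frequencies"
            )
        if np.any(np.diff(f) <= 0):
            raise ValidationError("bin_frequencies must be strictly increasing")
        if lab.size != c.shape[0]:
            raise ShapeError(
                f"{lab.size} labels for {c.shape[0]} trials"
            )
        self.coeffs = c
        self.bin_frequencies = f
        self.condition_labels = lab

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def is_source_level(self) -> bool:
        return self.coeffs.ndim == 2


def _conditioned_cholesky(cov: SensorCovariance, ridge: float) -> np.ndarray:
    """Cholesky factor of ``C + ridge*I``; refuses ill-conditioned input."""
    c = cov.matrix
    if ridge < 0:
        raise ValidationError("ridge must be non-negative")
    if ridge > 0:
        c = c + ridge * np.eye(c.shape[0])
    eigvals = linalg.eigvalsh(c)
    if eigvals[0] <= 0 or eigvals[-1] / eigvals[0] > COND_LIMIT:
        raise SingularCovarianceError(
            "sensor covariance is singular or ill-conditioned "
            f"(condition number {eigvals[-1] / max(eigvals[0], np.finfo(float).tiny):.3g}); "
            "supply a ridge or a better-estimated covariance"
        )
    return linalg.cholesky(c, lower=True)


def _solve_cov(chol: np.ndarray, b: np.ndarray) -> np.ndarray:
    return linalg.cho_solve((chol, True), b)


def select_orientation(
    leadfield: LeadField, cov: SensorCovariance, ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Orient a free-orientation lead field to maximise projected power.

    Returns ``(oriented_leadfield, orientation)`` where ``orientation`` is a
    unit 3-vector and ``oriented_leadfield = L @ orientation``.  Projected
    power under unit-gain weights is ``1 / (u^T L^T C^{-1} L u)``, so the
    optimum is the minor eigenvector of ``L^T C^{-1} L``.  The sign is fixed
    by making the first nonzero component of the orientation positive.
    """
    L = leadfield.matrix
    if L.shape[1] != 3:
        raise ShapeError("orientation selection requires a (channels, 3) lead field")
    chol = _conditioned_cholesky(cov, ridge)
    A = L.T @ _solve_cov(chol, L)
    A = 0.5 * (A + A.T)
    eigvals, eigvecs = linalg.eigh(A)
    # A rank-deficient lead field leaves a null orientation with (numerically)
    # infinite power and no identified direction.
    if eigvals[0] <= 1e-12 * max(eigvals[-1], np.finfo(float).tiny):
        raise InvalidLeadFieldError(
            f"lead field {leadfield.location_id!r} is rank deficient; "
            "source orientation is not identified"
        )
    u = eigvecs[:, 0]
    nz = np.flatnonzero(np.abs(u) > 0)
    if u[nz[0]] < 0:
        u = -u
    return L @ u, u


def lcmv_weights(
    oriented_leadfield: np.ndarray,
    cov: SensorCovariance,
    ridge: float = 0.0,
    orientation: np.ndarray | None = None,
    location_id: str = "",
) -> BeamformerWeights:
    """Unit-gain LCMV weights ``w = C^{-1} l / (l^T C^{-1} l)``."""
    l = np.asarray(oriented_leadfield, dtype=float).ravel()
    if l.size != cov.n_channels:
        raise ShapeError(
            f"lead field has {l.size} channels, covariance has {cov.n_channels}"
        )
    if not np.any(l):
        raise InvalidLeadFieldError("oriented lead field is identically zero")
    chol = _conditioned_cholesky(cov, ridge)
    ci_l = _solve_cov(chol, l)
    denom = float(l @ ci_l)
    if denom <= 0:
        raise SingularCovarianceError("l^T C^{-1} l is not positive")
    return BeamformerWeights(
        weights=ci_l / denom,
        oriented_leadfield=l,
        orientation=None if orientation is None else np.asarray(orientation, float),
        location_id=location_id,
    )


def project_trials(weights: BeamformerWeights, sensor: TrialSpectra) -> TrialSpectra:
    """Project sensor-level coefficients to one source location.

    The source estimate for trial ``i`` and bin ``j`` is ``w^T q_ij`` where
    ``q_ij`` is the vector of sensor coefficients.  Bin frequencies and
    condition labels carry over unchanged.
    """
    if sensor.coeffs.ndim != 3:
        raise ShapeError("project_trials expects sensor-level (trials, channels, bins)")
    if sensor.coeffs.shape[1] != weights.weights.size:
        raise ShapeError(
            f"{sensor.coeffs.shape[1]} channels in data, "
            f"{weights.weights.size} in weights"
        )
    source = np.einsum("c,tcb->tb", weights.weights, sensor.coeffs)
    return TrialSpectra(
        coeffs=source,
        bin_frequencies=sensor.bin_frequencies,
        condition_labels=sensor.condition_labels,
        location_id=weights.location_id,
    )
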