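"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the implementation's own code paths:
orientation selection is checked against a dense grid search on the unit
sphere, and the first canonical correlation against direct numerical
maximization of corr(Xa, Yb) by alternating least squares.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20130805)


def random_spd(rng: np.random.Generator, n: int, cond: float = 50.0) -> np.ndarray:
    """Random symmetric positive-definite matrix with bounded conditioning."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    eigs = np.geomspace(1.0, cond, n)
    return (Q * eigs) @ Q.T


def sphere_grid(n: int = 10_000) -> np.ndarray:
    """Near-uniform unit vectors on S^2 (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def brute_force_orientation(L: np.ndarray, C: np.ndarray, n_grid: int = 10_000):
    """Grid-search the orientation maximising LCMV projected power.

    Power for unit-gain weights is 1 / (u^T L^T C^{-1} L u); returns the
    best grid orientation and its power.
    """
    A = L.T @ np.linalg.solve(C, L)
    grid = sphere_grid(n_grid)
    quad = np.einsum("ni,ij,nj->n", grid, A, grid)
    best = np.argmin(quad)
    return grid[best], 1.0 / quad[best]


def projected_power(u: np.ndarray, L: np.ndarray, C: np.ndarray) -> float:
    A = L.T @ np.linalg.solve(C, L)
    return 1.0 / float(u @ A @ u)


def cca_rho1_direct(
    X: np.ndarray,
    Y: np.ndarray,
    n_restarts: int = 4,
    max_iter: int = 2000,
    tol: float = 1e-13,
    seed: int = 0,
) -> float:
    """First canonical correlation by direct maximization of corr(Xa, Yb).

    Alternating least squares: with one projection fixed, the optimal
    other projection is an ordinary regression.  Restarted from random
    points; returns the best correlation found.
    """
    rng = np.random.default_rng(seed)
    Xc = np.atleast_2d(X.astype(float))
    if Xc.shape[0] == 1:
        Xc = Xc.T
    Yc = np.atleast_2d(Y.astype(float))
    if Yc.shape[0] == 1:
        Yc = Yc.T
    Xc = Xc - Xc.mean(axis=0)
    Yc = Yc - Yc.mean(axis=0)

    def corr(a, b):
        u, v = Xc @ a, Yc @ b
        su, sv = np.linalg.norm(u), np.linalg.norm(v)
        if su == 0 or sv == 0:
            return 0.0
        return abs(float(u @ v) / (su * sv))

    best = 0.0
    for _ in range(n_restarts):
        a = rng.standard_normal(Xc.shape[1])
        prev = -1.0
        for _ in range(max_iter):
            u = Xc @ a
            nu = np.linalg.norm(u)
            if nu == 0:
                break
            b, *_ = np.linalg.lstsq(Yc, u / nu, rcond=None)
            v = Yc @ b
            nv = np.linalg.norm(v)
            if nv == 0:
                break
            a, *_ = np.linalg.lstsq(Xc, v / nv, rcond=None)
            r = corr(a, b)
            if abs(r - prev) < tol:
                break
            prev = r
        best = max(best, corr(a, b))
    return best
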