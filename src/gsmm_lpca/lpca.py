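"""Logistic principal component analysis of binary matrices.

Classical PCA projects data onto a low-rank subspace by minimising squared
error; for 0/1 data the analogous exponential-family formulation projects
*natural parameters* of a Bernoulli model and minimises Bernoulli deviance.
Each observed entry is first encoded as a saturated natural parameter

    Theta = m * (2X - 1)            (entries +m for 1, -m for 0)

for a tunable scale ``m`` controlling how extreme the saturated log-odds
are.  The rank-k reconstruction is

    Theta_hat = 1 mu^T + (Theta - 1 mu^T) U U^T

with a mean vector ``mu`` (length R) and an orthonormal loading matrix
``U`` (R x k), chosen to minimise the deviance

    D(X | Theta_hat) = -2 sum_{n,r} [ X_nr Theta_hat_nr
                                      - log(1 + exp(Theta_hat_nr)) ].

Model scores (the low-dimensional coordinates) are
``S = (Theta - 1 mu^T) U``.

The optimiser is a majorization-minimization (MM) scheme built on the
standard quadratic bound for the logistic log-partition (curvature 1/4):
given the current reconstruction, form the working matrix
``Z = Theta_hat + 4 (X - sigmoid(Theta_hat))`` and minimise the majorizing
least-squares problem in closed form, alternating a mean update and an
eigenvector update.  Every iteration provably decreases the deviance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .reaction_matrix import BinaryReactionMatrix

logger = logging.getLogger(__name__)

DEFAULT_M_GRID: tuple[float, ...] = tuple(float(m) for m in range(2, 13))


@dataclass
class LPCAConfig:
    """Settings for :func:`fit_lpca`.

    ``m`` may be a positive float or ``"auto"``; auto mode selects ``m``
    from ``m_grid`` by refitting at each candidate and keeping the deviance
    minimiser (ties go to the smallest ``m``).
    """

    k: int = 2
    m: float | str = 4.0
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0
    partial_eigen: bool = False
    m_grid: tuple[float, ...] = DEFAULT_M_GRID
    n_restarts: int = 0

    def validate(self, n: int, r: int) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k >= min(n, r):
            raise ValueError(f"k={self.k} must be < min(N, R) = {min(n, r)}")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.m != "auto" and not (isinstance(self.m, (int, float)) and self.m > 0):
            raise ValueError("m must be a positive number or 'auto'")


@dataclass
class LPCAModel:
    """Fitted logistic PCA: mean vector, loadings, scores and diagnostics."""

    mu: np.ndarray
    U: np.ndarray
    S: np.ndarray
    m: float
    deviance_trace: list[float]
    converged: bool
    n_iter: int
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)
    m_selection: str = "fixed"

    @property
    def k(self) -> int:
        return self.U.shape[1]

    @property
    def deviance(self) -> float:
        return self.deviance_trace[-1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.S, index=self.row_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.U, index=self.col_ids, columns=cols)

    def mu_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mu}, index=self.col_ids)


def saturated_parameters(X: BinaryReactionMatrix | np.ndarray, m: float) -> np.ndarray:
    """Natural parameters of the saturated Bernoulli model, ``m (2X - 1)``."""
    if m <= 0:
        raise ValueError("m must be positive")
    values = X.values if isinstance(X, BinaryReactionMatrix) else np.asarray(X)
    return m * (2.0 * values - 1.0)


def bernoulli_deviance(X: BinaryReactionMatrix | np.ndarray, theta_hat: np.ndarray) -> float:
    """Bernoulli deviance between 0/1 data and natural-parameter estimates.

    Uses the softplus identity ``log(1 + e^t) = max(t, 0) + log1p(e^{-|t|})``
    so the sum stays finite and accurate for |theta| up to several hundred.
    """
    values = X.values if isinstance(X, BinaryReactionMatrix) else np.asarray(X)
    theta_hat = np.asarray(theta_hat, dtype=float)
    if values.shape != theta_hat.shape:
        raise ValueError("shape mismatch between data and natural parameters")
    if not np.isfinite(theta_hat).all():
        raise ValueError("non-finite natural parameter")
    softplus = np.logaddexp(0.0, theta_hat)
    return float(-2.0 * np.sum(values * theta_hat - softplus))


def _theta_hat(theta: np.ndarray, mu: np.ndarray, U: np.ndarray) -> np.ndarray:
    centred = theta - mu
    return mu + (centred @ U) @ U.T


def _apply_sign_convention(U: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # per component: the largest-magnitude loading is made non-negative
    U = U.copy()
    S = S.copy()
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            S[:, j] = -S[:, j]
    return U, S


def _top_k_eigvecs(B: np.ndarray, k: int, partial: bool) -> np.ndarray:
    r = B.shape[0]
    if partial and k < r - 1:
        from scipy.sparse.linalg import eigsh

        # deterministic start vector: results must not depend on RNG state
        v0 = np.full(r, 1.0 / np.sqrt(r))
        vals, vecs = eigsh(B, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        return vecs[:, order]
    vals, vecs = np.linalg.eigh(B)
    return vecs[:, ::-1][:, :k]


def fit_lpca(
    X: BinaryReactionMatrix | np.ndarray,
    config: LPCAConfig | None = None,
    **overrides,
) -> LPCAModel:
    """Fit logistic PCA by monotone majorization-minimization.

    Parameters are taken from ``config`` (or a default :class:`LPCAConfig`)
    with keyword ``overrides`` applied on top, e.g. ``fit_lpca(X, k=2, m=4)``.

    The fit is deterministic: initialisation uses the column means of the
    saturated parameters and their top-k right singular vectors.  After
    convergence a sign convention is applied (per component, the
    largest-magnitude loading is non-negative), which makes repeated fits
    on identical input bit-stable.
    """
    config = config or LPCAConfig()
    if overrides:
        config = LPCAConfig(**{**config.__dict__, **overrides})
    values = X.values if isinstance(X, BinaryReactionMatrix) else np.asarray(X)
    row_ids = X.row_ids if isinstance(X, BinaryReactionMatrix) else [str(i) for i in range(values.shape[0])]
    col_ids = X.col_ids if isinstance(X, BinaryReactionMatrix) else [str(j) for j in range(values.shape[1])]
    n, r = values.shape
    config.validate(n, r)

    colsum = values.sum(axis=0)
    constant_cols = (colsum == 0) | (colsum == n)
    if constant_cols.all():
        raise ValueError("all columns are constant; nothing to fit")
    if constant_cols.any():
        warnings.warn(
            f"{int(constant_cols.sum())} constant column(s); consider a differential "
            "matrix (their mean parameters are clamped during fitting)",
            stacklevel=2,
        )

    if config.m == "auto":
        chosen, table = select_m(X, config.k, config.m_grid, config=config)
        model = _fit_at_m(values, row_ids, col_ids, config, float(chosen), constant_cols)
        model.m_selection = "auto-grid"
        logger.info("auto m selection table:\n%s", table)
        return model
    return _fit_at_m(values, row_ids, col_ids, config, float(config.m), constant_cols)


def _fit_at_m(
    values: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    config: LPCAConfig,
    m: float,
    constant_cols: np.ndarray,
) -> LPCAModel:
    """Run MM from the deterministic init plus any configured restarts.

    The deviance surface can hold several MM basins on very small matrices;
    seeded random restarts (``n_restarts > 0``) rerun the same monotone
    iteration from random starting points and keep the lowest-deviance
    solution (the deterministic start wins ties).
    """
    xv = values.astype(float)
    theta = m * (2.0 * xv - 1.0)

    # deterministic initialisation
    mu0 = theta.mean(axis=0)
    _, _, vt = np.linalg.svd(theta - mu0, full_matrices=False)
    best = _mm_loop(xv, theta, mu0, vt[: config.k].T, config, m, constant_cols)
    if config.n_restarts > 0:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_restarts):
            mu_r = rng.normal(0.0, m, size=theta.shape[1])
            q, _ = np.linalg.qr(rng.normal(size=(theta.shape[1], config.k)))
            cand = _mm_loop(xv, theta, mu_r, q, config, m, constant_cols)
            if cand[2][-1] < best[2][-1] - 1e-12:
                best = cand
    mu, U, trace, converged, it = best

    S = (theta - mu) @ U
    U, S = _apply_sign_convention(U, S)
    return LPCAModel(
        mu=mu,
        U=U,
        S=S,
        m=m,
        deviance_trace=trace,
        converged=converged,
        n_iter=it,
        row_ids=list(row_ids),
        col_ids=list(col_ids),
    )


def _mm_loop(
    xv: np.ndarray,
    theta: np.ndarray,
    mu: np.ndarray,
    U: np.ndarray,
    config: LPCAConfig,
    m: float,
    constant_cols: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    clamp = 10.0 * m
    trace = [bernoulli_deviance(xv, _theta_hat(theta, mu, U))]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        theta_hat = _theta_hat(theta, mu, U)
        Z = theta_hat + 4.0 * (xv - expit(theta_hat))

        # mean update: project the column means of (Z - Theta U U^T) onto
        # the orthogonal complement of range(U)
        M = Z - (theta @ U) @ U.T
        mbar = M.mean(axis=0)
        mu = mbar - U @ (U.T @ mbar)
        if constant_cols.any():
            mu[constant_cols] = np.clip(mu[constant_cols], -clamp, clamp)

        # loading update: top-k eigenvectors of the symmetric MM matrix
        theta_c = theta - mu
        z_c = Z - mu
        cross = theta_c.T @ z_c
        B = cross + cross.T - theta_c.T @ theta_c
        U = _top_k_eigvecs(B, config.k, config.partial_eigen)

        dev = bernoulli_deviance(xv, _theta_hat(theta, mu, U))
        trace.append(dev)
        prev = trace[-2]
        if prev - dev < config.tol * abs(prev):
            converged = True
            break

    return mu, U, trace, converged, it


def scores(model: LPCAModel, X: BinaryReactionMatrix | np.ndarray) -> np.ndarray:
    """Project (possibly new) binary rows onto fitted components.

    ``S = (m (2X - 1) - 1 mu^T) U`` — rows not used during fitting get the
    coordinates their reaction content implies under the fitted model.
    """
    values = X.values if isinstance(X, BinaryReactionMatrix) else np.asarray(X)
    if values.shape[1] != model.U.shape[0]:
        raise ValueError("column count does not match the fitted model")
    theta = model.m * (2.0 * values.astype(float) - 1.0)
    return (theta - model.mu) @ model.U


def fitted_probabilities(model: LPCAModel, X: BinaryReactionMatrix | np.ndarray) -> np.ndarray:
    """Element-wise Bernoulli probabilities, ``sigmoid(Theta_hat)``."""
    values = X.values if isinstance(X, BinaryReactionMatrix) else np.asarray(X)
    theta = model.m * (2.0 * values.astype(float) - 1.0)
    return expit(_theta_hat(theta, model.mu, model.U))


def select_m(
    X: BinaryReactionMatrix | np.ndarray,
    k: int,
    grid: Sequence[float] = DEFAULT_M_GRID,
    config: LPCAConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the saturation scale ``m`` minimising fitted deviance on a grid.

    Returns the chosen ``m`` (ties -> smallest) and the full (m, deviance,
    iterations) table for logging.
    """
    if len(grid) == 0:
        raise ValueError("m grid must be non-empty")
    if any(m <= 0 for m in grid):
        raise ValueError("all grid values must be positive")
    base = config or LPCAConfig(k=k)
    rows = []
    for m in sorted(grid):
        cfg = LPCAConfig(**{**base.__dict__, "k": k, "m": float(m)})
        model = fit_lpca(X, cfg)
        rows.append({"m": float(m), "deviance": model.deviance, "n_iter": model.n_iter})
    table = pd.DataFrame(rows)
    best = table.loc[table["deviance"].idxmin()]
    # sorted grid + idxmin => smallest m wins ties
    return float(best["m"]), table
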