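"""Node-wise L1-penalized lag-1 regression with corrected-AIC tuning.

The lag-1 network is estimated one node at a time: each item at day t is
regressed on all p items (itself included) at day t−1, the coefficients are
L1-penalized (LASSO) over a 100-point log-spaced penalty grid, and the
penalty is chosen per node by the corrected AIC with degrees of freedom
equal to the number of nonzero coefficients.  Both predictors and outcomes
are z-standardized over the lag-pair set, so the selected coefficients are
on a standardized, partial-correlation-like scale and comparable across
edges.  Edge weights are the penalized estimates themselves — no
post-selection re-fitting.

Lag pairs respect the calendar: under the default ``calendar`` policy, day d
is paired with day d+1 only when both are fully observed, so a missed diary
day breaks the run rather than silently lengthening the lag.  The
``sequential`` policy (consecutive observations regardless of gap) is
provided for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import lasso_path

from .detrend import aicc
from .network import LagNetwork
from .ratings import RatingMatrix

__all__ = [
    "LagPairSet",
    "LassoPath",
    "build_lag_pairs",
    "fit_node_lasso",
    "estimate_network",
    "LagNetworkEstimator",
]

logger = logging.getLogger(__name__)


@dataclass
class LagPairSet:
    """Aligned (yesterday, today) observation pairs, standardized per item."""

    pairs: list[tuple[pd.Timestamp, pd.Timestamp]]
    X: np.ndarray            # n_pairs × p, standardized values at t−1
    Y: np.ndarray            # n_pairs × p, standardized values at t
    items: list[str]
    x_scale: np.ndarray      # per-item SD used for X (0 ⇒ constant column)
    y_scale: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class LassoPath:
    """Full regularization path for one outcome node."""

    lambdas: np.ndarray          # decreasing penalty grid
    coefficients: np.ndarray     # n_lambdas × p
    aicc: np.ndarray             # per-lambda corrected AIC
    chosen_index: int

    @property
    def chosen_coefficients(self) -> np.ndarray:
        return self.coefficients[self.chosen_index]


def _standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores (population SD); constant columns become all-zero."""
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    out = np.zeros_like(mat)
    nz = sd > 0
    out[:, nz] = (mat[:, nz] - mean[nz]) / sd[nz]
    return out, sd


def build_lag_pairs(
    residuals: RatingMatrix, policy: str = "calendar"
) -> LagPairSet:
    """Build the (t−1, t) pair set from a detrended residual matrix.

    calendar : pair day d with d+1 only when both days are fully observed.
    sequential : pair consecutive fully-observed days regardless of the
        calendar gap between them.
    """
    if policy not in ("calendar", "sequential"):
        raise ValueError(f"policy must be 'calendar' or 'sequential', got {policy!r}")
    complete = residuals.day_complete
    obs_idx = np.flatnonzero(complete)
    pairs_idx: list[tuple[int, int]] = []
    if policy == "calendar":
        for d in obs_idx:
            if d + 1 < residuals.n_days and complete[d + 1]:
                pairs_idx.append((d, d + 1))
    else:
        pairs_idx = list(zip(obs_idx[:-1], obs_idx[1:]))
    if not pairs_idx:
        raise ValueError("no usable lag-1 pairs in the residual matrix")
    p = residuals.n_items
    if len(pairs_idx) < p + 2:
        logger.warning(
            "only %d lag pairs for %d predictors; estimates rely heavily on "
            "regularization", len(pairs_idx), p,
        )
    i0 = np.array([a for a, _ in pairs_idx])
    i1 = np.array([b for _, b in pairs_idx])
    X_raw = residuals.values[i0, :]
    Y_raw = residuals.values[i1, :]
    X, x_scale = _standardize(X_raw)
    Y, y_scale = _standardize(Y_raw)
    for j in np.flatnonzero(x_scale == 0):
        logger.warning("predictor %r constant over pair set; coefficients forced to 0",
                       residuals.items[j])
    pairs = [(residuals.days[a], residuals.days[b]) for a, b in pairs_idx]
    return LagPairSet(pairs=pairs, X=X, Y=Y, items=list(residuals.items),
                      x_scale=x_scale, y_scale=y_scale)


def fit_node_lasso(
    y: np.ndarray,
    X: np.ndarray,
    lambda_grid_size: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> LassoPath:
    """LASSO path for one outcome with AICc penalty selection.

    Minimizes ``||y − Xβ||² / (2n) + λ·||β||₁`` on a log-spaced grid from
    λ_max (the smallest penalty with an all-zero solution) down to
    ``lambda_min_ratio·λ_max``; AICc uses k = number of nonzero
    coefficients.  Ties prefer the larger penalty (sparser model).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    lam_max = float(np.max(np.abs(X.T @ y)) / n)
    if lam_max <= 0:  # outcome orthogonal to every predictor (or constant)
        lambdas = np.logspace(0, np.log10(lambda_min_ratio), lambda_grid_size)
        coefs = np.zeros((lambda_grid_size, X.shape[1]))
        crit = np.full(lambda_grid_size, aicc(n, float(y @ y), 0))
        return LassoPath(lambdas=lambdas, coefficients=coefs, aicc=crit,
                         chosen_index=0)
    lambdas = np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), lambda_grid_size
    )
    # tight tolerance: solutions must be independent of column order so
    # the estimated network is exactly permutation-equivariant
    _, coefs, _ = lasso_path(X, y, alphas=lambdas, max_iter=100_000, tol=1e-12)
    coefs = coefs.T  # n_lambdas × p, aligned with decreasing lambdas
    crit = np.empty(len(lambdas))
    for i, beta in enumerate(coefs):
        resid = y - X @ beta
        k = int(np.count_nonzero(beta))
        crit[i] = aicc(n, float(resid @ resid), k)
    chosen = int(np.argmin(crit))  # argmin takes the first = largest lambda on ties
    return LassoPath(lambdas=lambdas, coefficients=coefs, aicc=crit,
                     chosen_index=chosen)


class LagNetworkEstimator(BaseEstimator):
    """Sparse lag-1 network estimator for one person's residual series.

    Runs :func:`fit_node_lasso` once per item with all p items at t−1 as
    predictors and assembles the p × p coefficient matrix ``W_`` with
    ``W_[i, j]`` the selected coefficient of predictor i for outcome j
    (diagonal = autoregressive self-loops).

    Parameters
    ----------
    policy : {"calendar", "sequential"}, default "calendar"
        Lag-pair construction policy.
    lambda_grid_size : int, default 100
    lambda_min_ratio : float, default 1e-3
    criterion : {"aicc"}, default "aicc"
        Penalty selection criterion.

    Attributes
    ----------
    W_ : ndarray of shape (p, p)
        Standardized lag-1 coefficients, row = origin, column = destination.
    network_ : LagNetwork
        The same matrix wrapped with node labels and provenance.
    paths_ : list of LassoPath
        Per-outcome regularization paths.
    pairs_ : LagPairSet
    """

    def __init__(self, policy: str = "calendar", lambda_grid_size: int = 100,
                 lambda_min_ratio: float = 1e-3, criterion: str = "aicc"):
        self.policy = policy
        self.lambda_grid_size = lambda_grid_size
        self.lambda_min_ratio = lambda_min_ratio
        self.criterion = criterion

    def fit(self, residuals: RatingMatrix, y=None):
        if self.criterion != "aicc":
            raise ValueError(f"unsupported criterion {self.criterion!r}")
        if residuals.n_items < 2:
            raise ValueError("network estimation requires at least 2 items")
        ps = build_lag_pairs(residuals, policy=self.policy)
        p = len(ps.items)
        W = np.zeros((p, p))
        paths = []
        for j in range(p):
            try:
                path = fit_node_lasso(
                    ps.Y[:, j], ps.X,
                    lambda_grid_size=self.lambda_grid_size,
                    lambda_min_ratio=self.lambda_min_ratio,
                )
            except Exception as exc:  # annotate with the failing node
                raise RuntimeError(f"node-wise fit failed for item {ps.items[j]!r}") from exc
            paths.append(path)
            W[:, j] = path.chosen_coefficients
        self.pairs_ = ps
        self.paths_ = paths
        self.W_ = W
        self.network_ = LagNetwork(
            nodes=list(ps.items), W=W,
            provenance={
                "policy": self.policy,
                "criterion": self.criterion,
                "lambda_grid_size": self.lambda_grid_size,
                "lambda_min_ratio": self.lambda_min_ratio,
                "n_pairs": ps.n_pairs,
            },
        )
        return self


def estimate_network(
    residuals: RatingMatrix, policy: str = "calendar", criterion: str = "aicc",
) -> LagNetwork:
    """Estimate the regularized lag-1 network; see LagNetworkEstimator."""
    est = LagNetworkEstimator(policy=policy, criterion=criterion).fit(residuals)
    return est.network_
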