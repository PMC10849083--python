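"""Bezdek fuzzy-c-means (FCM) soft clustering.

FCM minimizes the fuzzifier-weighted sum of squared Euclidean distances

    J(U, V) = sum_i sum_t  u_it^m * ||x_i - v_t||^2

subject to u_it >= 0 and sum_t u_it = 1 for every datum i, by alternating
the closed-form centroid update

    v_t = sum_i u_it^m x_i / sum_i u_it^m

with the membership update

    u_it = [ sum_s ( ||x_i - v_t|| / ||x_i - v_s|| )^(2/(m-1)) ]^(-1).

The fuzzifier m > 1 controls softness; as m -> 1+ memberships harden and the
procedure approaches k-means (that limit is exposed as a separate flag, since
the membership formula is undefined at m = 1).  Iteration stops when the
largest elementwise membership change drops below epsilon, for all i and t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FCMConfig",
    "FuzzyPartition",
    "DegenerateClusterError",
    "fcm_objective",
    "fcm_update_centroids",
    "fcm_update_memberships",
    "fcm_fit",
]

_ROW_SUM_TOL = 1e-9


class DegenerateClusterError(RuntimeError):
    """A cluster lost all membership mass (its centroid is undefined)."""


@dataclass
class FCMConfig:
    """FCM hyperparameters.

    c:
        Number of clusters (>= 2).
    m:
        Fuzzifier, strictly > 1.  Defaults to the conventional 2.0.  Values
        just above 1 (e.g. 1 + 1e-6) approximate hard k-means; the exact
        k-means limit is requested with ``kmeans_limit=True``, which replaces
        the membership update with a hard nearest-centroid assignment.
    epsilon:
        Convergence threshold on the max elementwise membership change.
    max_iter:
        Iteration cap.
    seed:
        Seeds the random initial membership matrix (rows uniform on the
        probability simplex, i.e. symmetric Dirichlet(1)).
    """

    c: int
    m: float = 2.0
    epsilon: float = 1e-5
    max_iter: int = 300
    seed: int = 0
    kmeans_limit: bool = False

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if not self.m > 1:
            raise ValueError(
                "fuzzifier m must exceed 1 (use kmeans_limit=True for the "
                "hard-clustering limit)"
            )
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FuzzyPartition:
    """Fitted FCM state: memberships, centroids and the objective trace."""

    U: np.ndarray  # (n, c) memberships, rows sum to 1
    V: np.ndarray  # (c, d) centroids
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def c(self) -> int:
        return self.U.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Harden memberships to the modal cluster per datum."""
        return np.argmax(self.U, axis=1)


def _check_shapes(X: np.ndarray, U: np.ndarray | None, V: np.ndarray | None) -> None:
    if U is not None and U.shape[0] != X.shape[0]:
        raise ValueError(f"U has {U.shape[0]} rows but X has {X.shape[0]}")
    if V is not None and V.shape[1] != X.shape[1]:
        raise ValueError(f"V is {V.shape[1]}-dimensional but X is {X.shape[1]}-dimensional")
    if U is not None and V is not None and U.shape[1] != V.shape[0]:
        raise ValueError(f"U has {U.shape[1]} clusters but V has {V.shape[0]}")


def fcm_objective(X: np.ndarray, U: np.ndarray, V: np.ndarray, m: float) -> float:
    """J(U, V): the fuzzifier-weighted sum of squared Euclidean distances."""
    X, U, V = np.asarray(X, float), np.asarray(U, float), np.asarray(V, float)
    _check_shapes(X, U, V)
    if np.abs(U.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("membership rows must sum to 1")
    d2 = cdist(X, V, metric="sqeuclidean")
    return float(np.sum(U**m * d2))


def fcm_update_centroids(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    """Closed-form centroid update: fuzzified-membership weighted means."""
    X, U = np.asarray(X, float), np.asarray(U, float)
    _check_shapes(X, U, None)
    Um = U**m
    mass = Um.sum(axis=0)
    if np.any(mass == 0):
        dead = np.flatnonzero(mass == 0).tolist()
        raise DegenerateClusterError(f"clusters {dead} have zero total membership")
    return (Um.T @ X) / mass[:, None]


def fcm_update_memberships(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    """Membership update; rows sum to 1.

    A datum coinciding with one or more centroids takes membership split
    equally among the zero-distance clusters and 0 elsewhere (the continuity
    convention; the printed formula is undefined there).
    """
    if not m > 1:
        raise ValueError("membership update requires m > 1")
    X, V = np.asarray(X, float), np.asarray(V, float)
    _check_shapes(X, None, V)
    d2 = cdist(X, V, metric="sqeuclidean")
    U = np.zeros_like(d2)
    zero_rows = (d2 == 0).any(axis=1)
    if zero_rows.any():
        z = d2[zero_rows] == 0
        U[zero_rows] = z / z.sum(axis=1, keepdims=True)
    reg = ~zero_rows
    if reg.any():
        # u_it ∝ d_it^(-2/(m-1)); normalize by the row minimum first so the
        # power never overflows even for m barely above 1 (ratios >= 1 raised
        # to a large negative exponent underflow harmlessly to 0)
        d2r = d2[reg]
        ratio = d2r / d2r.min(axis=1, keepdims=True)
        w = ratio ** (-1.0 / (m - 1.0))
        U[reg] = w / w.sum(axis=1, keepdims=True)
    return U


def _hard_memberships(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    d2 = cdist(X, V, metric="sqeuclidean")
    U = np.zeros_like(d2)
    U[np.arange(len(X)), d2.argmin(axis=1)] = 1.0
    return U


def fcm_fit(X: np.ndarray, config: FCMConfig) -> FuzzyPartition:
    """Alternating minimization from a seeded random membership matrix.

    Stops when ``max_it |u_it^(p+1) - u_it^(p)| < epsilon`` or after
    ``max_iter`` iterations; the returned partition carries the full
    objective trace, which is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d array (n, d)")
    n = X.shape[0]
    if n < config.c:
        raise ValueError(f"need at least c={config.c} data points, got {n}")

    rng = np.random.default_rng(config.seed)
    U = rng.dirichlet(np.ones(config.c), size=n)

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        V = fcm_update_centroids(X, U, config.m)
        if config.kmeans_limit:
            U_new = _hard_memberships(X, V)
        else:
            U_new = fcm_update_memberships(X, V, config.m)
        trace.append(fcm_objective(X, U_new, V, config.m))
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < config.epsilon:
            converged = True
            break

    assert np.abs(U.sum(axis=1) - 1.0).max() < _ROW_SUM_TOL
    return FuzzyPartition(
        U=U, V=V, objective_trace=trace, n_iter=n_iter, converged=converged
    )
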