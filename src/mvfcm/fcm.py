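"""Single-view fuzzy c-means (FCM).

FCM minimizes ``J = sum_i sum_j u_ij^m ||x_j - z_i||^2`` over column-stochastic
memberships ``U`` and centers ``Z`` by alternating the two closed-form block
minimizers: centers are the u^m-weighted means of the data and memberships are
inverse-distance allocations with exponent ``1/(m-1)``.  The iteration stops
when the objective changes by less than ``tol`` or after ``max_iter`` rounds.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import (ClusterCenters, DegenerateClusterError, FitConfig,
                   MembershipMatrix, MultiViewData, SegmentationResult)

__all__ = [
    "squared_distances",
    "fcm_objective",
    "fcm_update_centers",
    "fcm_update_memberships",
    "fcm_fit",
    "init_memberships",
]


def squared_distances(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shaped (C, N) for (N, p) data."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if x.shape[1] != centers.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: data has p={x.shape[1]}, "
            f"centers have p={centers.shape[1]}")
    # ||x||^2 + ||z||^2 - 2 z.x, clipped against tiny negative round-off
    d2 = (np.sum(centers ** 2, axis=1)[:, None]
          + np.sum(x ** 2, axis=1)[None, :]
          - 2.0 * centers @ x.T)
    return np.maximum(d2, 0.0)


def fcm_objective(x, centers, membership, m: float = 2.0) -> float:
    """Evaluate J = sum u^m d^2 for one view."""
    u = np.asarray(membership, dtype=float)
    d2 = squared_distances(x, centers)
    if u.shape != d2.shape:
        raise ValueError(
            f"membership shape {u.shape} does not match (C, N)={d2.shape}")
    return float(np.sum(u ** m * d2))


def _weighted_centers(x: np.ndarray, weights: np.ndarray,
                      on_empty: str = "raise") -> np.ndarray:
    """Centers as weight-normalized means; ``weights`` is (C, N), >= 0.

    ``on_empty="reseed"`` relocates a zero-weight cluster's center onto the
    sample whose best membership weight is lowest (the least-well-explained
    sample), keeping the number of clusters fixed.
    """
    totals = weights.sum(axis=1)
    empty = np.flatnonzero(totals <= 0)
    if empty.size and on_empty == "raise":
        raise DegenerateClusterError(
            f"clusters {empty.tolist()} have zero total membership weight")
    safe = np.where(totals > 0, totals, 1.0)
    z = (weights @ x) / safe[:, None]
    if empty.size:
        # least-covered samples first; one distinct sample per empty cluster
        order = np.argsort(weights.max(axis=0))
        for k, i in enumerate(empty):
            z[i] = x[order[k % len(order)]]
    return z


def fcm_update_centers(x, membership, m: float = 2.0,
                       on_empty: str = "raise") -> np.ndarray:
    """Closed-form center update: z_i = sum_j u_ij^m x_j / sum_j u_ij^m."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    u = np.asarray(membership, dtype=float)
    if u.shape[1] != x.shape[0]:
        raise ValueError(
            f"membership has N={u.shape[1]} columns but data has "
            f"N={x.shape[0]} rows")
    return _weighted_centers(x, u ** m, on_empty=on_empty)


def fcm_update_memberships(distances: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Closed-form membership update from squared distances (C, N).

    u_ij = 1 / sum_r (d2_ij / d2_rj)^(1/(m-1)).  A zero (or overflowing)
    distance is the analytic limit: full membership split equally among the
    zero-distance centers of that column.
    """
    d2 = np.asarray(distances, dtype=float)
    if (d2 < 0).any():
        raise ValueError("squared distances must be non-negative")
    expo = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.where(d2 > 0, d2, 1.0) ** (-expo)
    inv[d2 <= 0] = np.inf
    hard = ~np.isfinite(inv)
    u = np.empty_like(d2)
    cols = hard.any(axis=0)
    if cols.any():
        share = hard[:, cols].astype(float)
        u[:, cols] = share / share.sum(axis=0, keepdims=True)
    soft = ~cols
    if soft.any():
        block = inv[:, soft]
        u[:, soft] = block / block.sum(axis=0, keepdims=True)
    return u


def init_memberships(rng: np.random.Generator, n_clusters: int,
                     n_samples: int, n_views: int = 1) -> np.ndarray:
    """Random column-stochastic init, Dirichlet(1,...,1) per column.

    Returns an array shaped (V, C, N).  Shared by every algorithm so that
    reduction tests can start all of them from identical partitions.
    """
    g = rng.standard_exponential(size=(n_views, n_clusters, n_samples))
    return g / g.sum(axis=1, keepdims=True)


def fcm_fit(data, config: FitConfig,
            init_membership: Optional[np.ndarray] = None,
            iteration_hook=None) -> SegmentationResult:
    """Run FCM to convergence on a single-view dataset.

    ``data`` may be a plain (N, p) matrix or a V=1 :class:`MultiViewData`.
    ``init_membership`` overrides the seeded random initialization (used by
    reduction tests).  ``iteration_hook(it, membership, centers)`` is called
    after every full iteration.
    """
    if isinstance(data, MultiViewData):
        if data.n_views != 1:
            raise ValueError("fcm_fit is single-view; got "
                             f"{data.n_views} views (use the multi-view fits)")
        x = data.views[0]
        sample_shape = data.sample_shape
    else:
        x = np.atleast_2d(np.asarray(data, dtype=float))
        sample_shape = None
    n = x.shape[0]
    c = config.n_clusters
    if c > n:
        raise ValueError(f"n_clusters={c} exceeds n_samples={n}")
    m = config.fuzzifier

    if init_membership is None:
        rng = np.random.default_rng(config.seed)
        u = init_memberships(rng, c, n, 1)[0]
    else:
        u = np.array(init_membership, dtype=float)

    trace: list[float] = []
    converged = False
    n_iter = 0
    z = np.zeros((c, x.shape[1]))
    for it in range(config.max_iter):
        z = fcm_update_centers(x, u, m, on_empty="reseed")
        d2 = squared_distances(x, z)
        u = fcm_update_memberships(d2, m)
        j = float(np.sum(u ** m * d2))
        trace.append(j)
        n_iter = it + 1
        if iteration_hook is not None:
            iteration_hook(it, u, z)
        if it > 0 and abs(trace[-2] - j) < config.tol:
            converged = True
            break

    membership = MembershipMatrix(u)
    return SegmentationResult(
        fused_membership=membership,
        labels=membership.labels(),
        per_view_membership=[membership],
        centers=ClusterCenters([z]),
        weights=None,
        objective_trace=trace,
        converged=converged,
        n_iter=n_iter,
        params={"algorithm": "fcm", "m": m, "tol": config.tol,
                "seed": config.seed, "sample_shape": sample_shape},
    )
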