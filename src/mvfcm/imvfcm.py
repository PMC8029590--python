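"""Multi-view fuzzy c-means with adaptive, entropy-regularized view weights.

The model keeps one fuzzy partition ``U_t`` per view and one shared set of
per-view cluster centers ``z_{i,v}``, and learns a ``V x V`` row-stochastic
weight matrix ``W`` whose entry ``w_{v,t}`` measures how much view ``v``'s
clustering task trusts partition ``t``.  The objective is

    J = sum_v sum_i sum_j sum_t  w_{v,t} u_{ij,t}^m d2_{ij,v}
        + gamma * sum_v sum_t w_{v,t} log w_{v,t}

with column-stochastic memberships and row-stochastic weights.  The entropy
term (natural log, 0*log 0 = 0) is a temperature-``gamma`` regularizer: the
weight update is a row-wise softmax of the negative partition-to-view scatter
``S_{v,t} = sum_{ij} u_{ij,t}^m d2_{ij,v}``, so small ``gamma`` concentrates
each row on the best-fitting partition and large ``gamma`` flattens the rows
toward uniform.

All three block updates (centers, memberships, weights) are the exact
constrained minimizers of J in their block, so J is non-increasing across
iterations.  After convergence the per-view partitions are fused into one
partition by the weighted average ``sum_t a_t U_t`` with ``a_t = mean_v
w_{v,t}``, and crisp labels are its per-column argmax.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import xlogy

from .core import (ClusterCenters, FitConfig, MembershipMatrix, MultiViewData,
                   SegmentationResult, ViewWeightMatrix)
from .fcm import (_weighted_centers, fcm_update_memberships, init_memberships,
                  squared_distances)

__all__ = [
    "imv_objective",
    "imv_update_centers",
    "imv_update_memberships",
    "imv_update_weights",
    "weights_from_scatter",
    "partition_scatter",
    "imv_ensemble",
    "initial_weights",
    "imv_fit",
]


def _stack_distances(data: MultiViewData, centers) -> np.ndarray:
    return np.stack([squared_distances(data.views[v], centers[v])
                     for v in range(data.n_views)])


def partition_scatter(distances_all_views: np.ndarray,
                      memberships: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Scatter matrix S with S[v, t] = sum_{ij} u_{ij,t}^m d2_{ij,v}.

    Row v profiles how well each partition t explains view v's geometry;
    smaller is better.
    """
    u = np.asarray(memberships, dtype=float)
    d2 = np.asarray(distances_all_views, dtype=float)
    return np.einsum("tcn,vcn->vt", u ** m, d2)


def imv_objective(data, centers, memberships, weights, m: float = 2.0,
                  gamma: float = 1.0) -> float:
    """Evaluate the weighted-scatter + entropy objective.

    ``gamma`` must be positive; the entropy term uses the natural log with the
    convention 0*log 0 = 0.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if not isinstance(data, MultiViewData):
        data = MultiViewData.from_matrix(data)
    if isinstance(centers, ClusterCenters):
        centers = centers.per_view
    w = np.asarray(weights, dtype=float)
    d2 = _stack_distances(data, centers)
    s = partition_scatter(d2, memberships, m)
    return float(np.sum(w * s) + gamma * xlogy(w, w).sum())


def imv_update_centers(data: MultiViewData, memberships, weights,
                       m: float = 2.0, on_empty: str = "raise") -> list[np.ndarray]:
    """Center update: z_{i,v} = sum_{j,t} w_{v,t} u_{ij,t}^m x_{j,v} / (same weights).

    With V = 1 this is exactly the single-view FCM center update.
    """
    u = np.asarray(memberships, dtype=float)
    w = np.asarray(weights, dtype=float)
    combined = np.einsum("vt,tcn->vcn", w, u ** m)
    return [_weighted_centers(data.views[v], combined[v], on_empty=on_empty)
            for v in range(data.n_views)]


def imv_update_memberships(distances_all_views: np.ndarray, weights,
                           m: float = 2.0) -> np.ndarray:
    """Membership update per partition t from w-aggregated squared distances.

    Partition t sees the metric ``D_t = sum_v w_{v,t} d2_v`` (column t of W
    picks how much each view's geometry matters to it) and then follows the
    single-view closed form with exponent 1/(m-1).
    """
    d2 = np.asarray(distances_all_views, dtype=float)
    w = np.asarray(weights, dtype=float)
    aggregated = np.einsum("vt,vcn->tcn", w, d2)
    return np.stack([fcm_update_memberships(aggregated[t], m)
                     for t in range(aggregated.shape[0])])


def weights_from_scatter(scatter: np.ndarray, gamma: float) -> np.ndarray:
    """Row-wise softmax of -S/gamma, computed with max-subtraction.

    This is the exact minimizer of ``sum_t w_t S_{v,t} + gamma sum_t w_t log
    w_t`` over each row's simplex, and is invariant to subtracting the row
    maximum of ``-S/gamma`` (the overflow-safe evaluation).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    a = -np.asarray(scatter, dtype=float) / gamma
    a -= a.max(axis=1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=1, keepdims=True)


def imv_update_weights(distances_all_views, memberships, m: float = 2.0,
                       gamma: float = 1.0) -> np.ndarray:
    """Weight update: row v is softmax_t(-S_{v,t}/gamma)."""
    s = partition_scatter(distances_all_views, memberships, m)
    return weights_from_scatter(s, gamma)


def imv_ensemble(memberships, weights) -> tuple[np.ndarray, np.ndarray]:
    """Fuse per-view partitions into the final partition matrix.

    The fused matrix is ``sum_t a_t U_t`` with ``a_t = sum_v w_{v,t} / V``
    (the denominator ``sum_t sum_v w_{v,t}`` equals V because W rows are
    stochastic), hence itself column-stochastic; crisp labels are the
    per-column argmax over clusters.
    """
    u = np.asarray(memberships, dtype=float)
    w = np.asarray(weights, dtype=float)
    a = w.sum(axis=0) / w.sum()
    fused = np.einsum("t,tcn->cn", a, u)
    return fused, np.argmax(fused, axis=0)


def initial_weights(n_views: int, scheme: str = "diagonal",
                    rng: Optional[np.random.Generator] = None,
                    diag: float = 0.5) -> np.ndarray:
    """Initial V x V row-stochastic weight matrix.

    "diagonal" (default) mixes the identity with the uniform matrix,
    ``W0 = diag * I + (1 - diag)/V * J``: partition t starts anchored to view
    t, which is what makes the rows of W separate views by their clustering
    contribution.  A fully uniform start is a fixed point of the coupled
    updates (all partitions collapse onto one matrix and W stays uniform), so
    "uniform" is provided only for study.  "random" draws each row from a
    Dirichlet(1,...,1) using ``rng``.
    """
    v = n_views
    if scheme == "uniform":
        return np.full((v, v), 1.0 / v)
    if scheme == "diagonal":
        return diag * np.eye(v) + (1.0 - diag) / v * np.ones((v, v))
    if scheme == "random":
        if rng is None:
            rng = np.random.default_rng()
        g = rng.standard_exponential(size=(v, v))
        return g / g.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown weight init scheme {scheme!r}")


def _auto_gamma(scatter: np.ndarray) -> float:
    """Data-driven temperature: mean row range of S (fallbacks: mean S, 1.0).

    The softmax contrast per row is (max S - min S)/gamma, so this choice puts
    the argument spread at order one — adaptive but not winner-take-all.
    """
    ranges = scatter.max(axis=1) - scatter.min(axis=1)
    g = float(ranges.mean())
    if g <= 0:
        g = float(scatter.mean())
    if g <= 0:
        g = 1.0
    return g


def imv_fit(data, config: FitConfig,
            init_membership: Optional[np.ndarray] = None,
            init_weight: Optional[np.ndarray] = None,
            iteration_hook=None) -> SegmentationResult:
    """Fit the adaptive-weight multi-view model.

    One iteration updates centers, then memberships, then weights (each the
    exact minimizer of its block), then records the objective; the loop stops
    when |J_{l+1} - J_l| < tol or at ``max_iter``.  With ``config.gamma=None``
    the temperature is set once, at the first weight update, to the mean row
    range of the scatter matrix (recorded in ``result.params["gamma"]``).

    ``init_membership`` is a (V, C, N) stack overriding the seeded Dirichlet
    initialization; ``init_weight`` overrides the weight-matrix init.
    ``iteration_hook(it, memberships, centers, weights)`` runs after every
    iteration.  With V = 1 the fit follows exactly the same iterates as
    :func:`mvfcm.fcm.fcm_fit` from the same seed.
    """
    if not isinstance(data, MultiViewData):
        data = MultiViewData.from_matrix(data)
    n, v_count, c, m = data.n_samples, data.n_views, config.n_clusters, config.fuzzifier
    if c > n:
        raise ValueError(f"n_clusters={c} exceeds n_samples={n}")

    rng = np.random.default_rng(config.seed)
    if init_membership is None:
        u = init_memberships(rng, c, n, v_count)
    else:
        u = np.array(init_membership, dtype=float)
    if init_weight is None:
        w = initial_weights(v_count, config.weight_init, rng=rng)
    else:
        w = np.array(init_weight, dtype=float)

    gamma = config.gamma
    trace: list[float] = []
    converged = False
    n_iter = 0
    centers = [np.zeros((c, p)) for p in data.view_dims]
    for it in range(config.max_iter):
        centers = imv_update_centers(data, u, w, m, on_empty="reseed")
        d2 = _stack_distances(data, centers)
        u = imv_update_memberships(d2, w, m)
        s = partition_scatter(d2, u, m)
        if gamma is None:
            gamma = _auto_gamma(s)
        w = weights_from_scatter(s, gamma)
        j = float(np.sum(w * s) + gamma * xlogy(w, w).sum())
        trace.append(j)
        n_iter = it + 1
        if iteration_hook is not None:
            iteration_hook(it, u, centers, w)
        if it > 0 and abs(trace[-2] - j) < config.tol:
            converged = True
            break

    fused, labels = imv_ensemble(u, w)
    return SegmentationResult(
        fused_membership=MembershipMatrix(fused),
        labels=labels,
        per_view_membership=[MembershipMatrix(u[t]) for t in range(v_count)],
        centers=ClusterCenters(centers),
        weights=ViewWeightMatrix(w),
        objective_trace=trace,
        converged=converged,
        n_iter=n_iter,
        params={"algorithm": "imvfcm", "m": m, "gamma": gamma,
                "tol": config.tol, "seed": config.seed,
                "weight_init": config.weight_init,
                "sample_shape": data.sample_shape},
    )
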