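"""CoFKM: collaborative multi-view fuzzy k-means.

Each view keeps its own partition, but the objective couples them: view v's
clustering uses a fused coefficient that mixes its own memberships with the
other views' at strength eta in [0, (V-1)/V].  Per-view partitions are fused
into one matrix by an elementwise geometric mean.

The printed membership update is the m = 2 instantiation; for other m the
update generalizes with the usual 1/(m-1) exponent (logged when that happens).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .core import (ClusterCenters, FitConfig, MembershipMatrix, MultiViewData,
                   SegmentationResult)
from .fcm import (_weighted_centers, fcm_update_memberships, init_memberships,
                  squared_distances)

__all__ = [
    "cofkm_fused_membership",
    "cofkm_update_centers",
    "cofkm_update_memberships",
    "cofkm_geometric_ensemble",
    "cofkm_fit",
]

log = logging.getLogger(__name__)


def _check_eta(eta: float, n_views: int) -> None:
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if eta > 0 and n_views < 2:
        raise ValueError("eta > 0 requires at least two views")
    if n_views >= 2 and eta > (n_views - 1) / n_views + 1e-12:
        raise ValueError(
            f"eta={eta} outside [0, (V-1)/V] for V={n_views}")


def cofkm_fused_membership(memberships: np.ndarray, eta: float, m: float,
                           view: int) -> np.ndarray:
    """Fused coefficient for one view: (1-eta) u_v^m + eta/(V-1) sum_{v'!=v} u_v'^m."""
    u = np.asarray(memberships, dtype=float)
    v_count = u.shape[0]
    _check_eta(eta, v_count if eta > 0 else max(v_count, 1))
    um = u ** m
    if eta == 0 or v_count == 1:
        return um[view]
    others = um.sum(axis=0) - um[view]
    return (1.0 - eta) * um[view] + eta / (v_count - 1) * others


def cofkm_update_centers(data: MultiViewData, memberships: np.ndarray,
                         eta: float, m: float = 2.0,
                         on_empty: str = "raise") -> list[np.ndarray]:
    """Per-view center update weighted by the fused coefficients."""
    u = np.asarray(memberships, dtype=float)
    centers = []
    for v in range(data.n_views):
        w = cofkm_fused_membership(u, eta, m, v)
        centers.append(_weighted_centers(data.views[v], w, on_empty=on_empty))
    return centers


def cofkm_update_memberships(distances_all_views: np.ndarray, eta: float,
                             m: float = 2.0) -> np.ndarray:
    """Per-view membership update from the eta-blended squared distances.

    For view v the effective squared distance is
    ``(1-eta) d2_v + eta/(V-1) sum_{v'!=v} d2_v'``; memberships then follow the
    single-view closed form.  At eta = 0 this is exactly the FCM update per view.
    """
    d2 = np.asarray(distances_all_views, dtype=float)
    v_count = d2.shape[0]
    _check_eta(eta, v_count)
    if m != 2.0:
        log.info("CoFKM membership update generalized to m=%s with "
                 "exponent 1/(m-1); the printed rule is the m=2 case", m)
    if eta == 0 or v_count == 1:
        blended = d2
    else:
        others = d2.sum(axis=0, keepdims=True) - d2
        blended = (1.0 - eta) * d2 + eta / (v_count - 1) * others
    return np.stack([fcm_update_memberships(blended[v], m)
                     for v in range(v_count)])


def cofkm_geometric_ensemble(memberships) -> np.ndarray:
    """Elementwise geometric mean of the V per-view partitions.

    Not column-stochastic in general; callers renormalize when a proper
    partition is needed (argmax labels are invariant to positive column
    rescaling).
    """
    u = np.asarray(memberships, dtype=float)
    if u.ndim == 2:
        u = u[None]
    v_count = u.shape[0]
    return np.prod(u, axis=0) ** (1.0 / v_count)


def _fused_partition(memberships: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    raw = cofkm_geometric_ensemble(memberships)
    labels = np.argmax(raw, axis=0)
    sums = raw.sum(axis=0)
    fused = np.where(sums > 0, raw / np.where(sums > 0, sums, 1.0),
                     np.asarray(memberships).mean(axis=0))
    # columns where every cluster had an absorbing zero fall back to the
    # arithmetic mean of the views (rare; keeps the partition well defined)
    dead = sums <= 0
    if dead.any():
        labels[dead] = np.argmax(fused[:, dead], axis=0)
    return fused, labels


def cofkm_fit(data, config: FitConfig,
              init_membership: Optional[np.ndarray] = None,
              iteration_hook=None) -> SegmentationResult:
    """Alternate the CoFKM center/membership updates until the objective settles.

    The objective is sum over views of the fused coefficients times squared
    distances.  Monotonicity under the coupled updates is not guaranteed and is
    logged, not asserted.
    """
    if not isinstance(data, MultiViewData):
        data = MultiViewData.from_matrix(data)
    n, v_count, c, m = data.n_samples, data.n_views, config.n_clusters, config.fuzzifier
    if c > n:
        raise ValueError(f"n_clusters={c} exceeds n_samples={n}")
    _check_eta(config.eta, v_count)
    eta = config.eta

    if init_membership is None:
        rng = np.random.default_rng(config.seed)
        u = init_memberships(rng, c, n, v_count)
    else:
        u = np.array(init_membership, dtype=float)

    trace: list[float] = []
    converged = False
    n_iter = 0
    centers = [np.zeros((c, p)) for p in data.view_dims]
    for it in range(config.max_iter):
        centers = cofkm_update_centers(data, u, eta, m, on_empty="reseed")
        d2 = np.stack([squared_distances(data.views[v], centers[v])
                       for v in range(v_count)])
        u = cofkm_update_memberships(d2, eta, m)
        j = float(sum(np.sum(cofkm_fused_membership(u, eta, m, v) * d2[v])
                      for v in range(v_count)))
        trace.append(j)
        n_iter = it + 1
        if iteration_hook is not None:
            iteration_hook(it, u, centers)
        if it > 0:
            if j > trace[-2] + 1e-9 * max(1.0, abs(trace[-2])):
                log.info("CoFKM objective increased at iteration %d "
                         "(%.6g -> %.6g)", it, trace[-2], j)
            if abs(trace[-2] - j) < config.tol:
                converged = True
                break

    fused, labels = _fused_partition(u)
    return SegmentationResult(
        fused_membership=MembershipMatrix(fused),
        labels=labels,
        per_view_membership=[MembershipMatrix(u[v]) for v in range(v_count)],
        centers=ClusterCenters(centers),
        weights=None,
        objective_trace=trace,
        converged=converged,
        n_iter=n_iter,
        params={"algorithm": "cofkm", "m": m, "eta": eta, "tol": config.tol,
                "seed": config.seed, "sample_shape": data.sample_shape},
    )
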