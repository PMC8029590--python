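"""Core data containers shared by every clustering routine.

The data model: ``N`` samples observed in ``V`` views, view ``v`` having its
own feature dimension ``p_v``.  Fuzzy partitions are ``C x N`` matrices whose
columns live on the probability simplex; view-importance weights form a
``V x V`` row-stochastic matrix where entry ``(v, t)`` is the importance of
view ``t``'s partition inside view ``v``'s clustering task.  When the samples
are image pixels, sample ``j`` is pixel ``(r, c)`` with ``j = r * width + c``
(row-major).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: absolute tolerance for the simplex constraints (column sums of a
#: membership matrix, row sums of a view-weight matrix)
STOCHASTIC_ATOL = 1e-9


class DegenerateClusterError(ValueError):
    """Raised when a cluster ends up with zero total membership weight."""


def _as_feature_matrix(a, name: str = "view") -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (n_samples, n_features) array, "
                         f"got ndim={arr.ndim}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class MultiViewData:
    """N samples described by V feature views.

    Parameters
    ----------
    views:
        List of ``V`` matrices; view ``v`` is shaped ``(N, p_v)``.  1-D arrays
        are promoted to single-column matrices.
    sample_shape:
        Optional ``(H, W)`` recorded when the samples are the pixels of an
        image (``N = H * W``, row-major order).
    """

    views: Sequence[np.ndarray]
    sample_shape: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.views) < 1:
            raise ValueError("MultiViewData needs at least one view")
        self.views = [_as_feature_matrix(v, f"view {i}")
                      for i, v in enumerate(self.views)]
        n = self.views[0].shape[0]
        if n < 1:
            raise ValueError("MultiViewData needs at least one sample")
        for i, v in enumerate(self.views):
            if v.shape[0] != n:
                raise ValueError(
                    f"view {i} has {v.shape[0]} rows, expected {n}")
        if self.sample_shape is not None:
            h, w = self.sample_shape
            if h * w != n:
                raise ValueError(
                    f"sample_shape {self.sample_shape} incompatible with "
                    f"N={n}")
            self.sample_shape = (int(h), int(w))

    @classmethod
    def from_matrix(cls, x, sample_shape=None) -> "MultiViewData":
        """Wrap a single feature matrix as the V=1 case."""
        return cls(views=[x], sample_shape=sample_shape)

    @property
    def n_samples(self) -> int:
        return self.views[0].shape[0]

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def view_dims(self) -> tuple[int, ...]:
        return tuple(v.shape[1] for v in self.views)


@dataclass
class ValidationReport:
    """Outcome of a stochasticity/range check; falsy when violated."""

    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate(values, kind: str = "membership",
             atol: float = STOCHASTIC_ATOL) -> ValidationReport:
    """Check the simplex constraints of a membership or view-weight matrix.

    ``kind="membership"`` checks columns sum to 1; ``kind="weights"`` checks
    rows sum to 1.  Entries must be finite and in ``[0, 1]``.  The report
    lists every violated constraint with its location.
    """
    arr = np.asarray(values, dtype=float)
    violations: list[str] = []
    if arr.ndim != 2:
        return ValidationReport(False, [f"expected a matrix, got ndim={arr.ndim}"])
    bad = ~np.isfinite(arr)
    if bad.any():
        locs = np.argwhere(bad)[:5]
        violations.append(
            "non-finite entries at " + ", ".join(map(str, map(tuple, locs))))
    else:
        low = arr < -atol
        high = arr > 1 + atol
        for mask, word in ((low, "< 0"), (high, "> 1")):
            if mask.any():
                locs = np.argwhere(mask)[:5]
                violations.append(
                    f"entries {word} at " + ", ".join(map(str, map(tuple, locs))))
        if kind == "membership":
            sums = arr.sum(axis=0)
            off = np.abs(sums - 1) > atol
            for j in np.flatnonzero(off)[:5]:
                violations.append(f"column {j} sums to {sums[j]:.12g}")
        elif kind == "weights":
            sums = arr.sum(axis=1)
            off = np.abs(sums - 1) > atol
            for v in np.flatnonzero(off)[:5]:
                violations.append(f"row {v} sums to {sums[v]:.12g}")
        else:
            raise ValueError(f"unknown kind {kind!r}")
    return ValidationReport(not violations, violations)


@dataclass
class MembershipMatrix:
    """C x N fuzzy partition; each column is a distribution over clusters."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_clusters(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> ValidationReport:
        return validate(self.values, kind="membership")

    def labels(self) -> np.ndarray:
        return np.argmax(self.values, axis=0)


@dataclass
class ViewWeightMatrix:
    """V x V row-stochastic matrix; entry (v, t) weights partition t in view v."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_views(self) -> int:
        return self.values.shape[0]

    def validate(self) -> ValidationReport:
        return validate(self.values, kind="weights")


@dataclass
class ClusterCenters:
    """Per-view cluster centers: view v holds a (C, p_v) matrix."""

    per_view: Sequence[np.ndarray]

    def __post_init__(self) -> None:
        self.per_view = [_as_feature_matrix(z, f"centers view {i}")
                         for i, z in enumerate(self.per_view)]
        cs = {z.shape[0] for z in self.per_view}
        if len(cs) != 1:
            raise ValueError(f"inconsistent cluster counts across views: {cs}")

    @property
    def n_clusters(self) -> int:
        return self.per_view[0].shape[0]


@dataclass
class FitConfig:
    """Shared fitting parameters.

    ``fuzzifier`` is the fuzziness exponent m > 1 (default 2); ``tol`` is the
    objective-difference stopping threshold ε (default 0.001) and ``max_iter``
    the iteration cap l (default 100).  ``gamma`` is the entropy-regularization
    temperature of the adaptive view weights (multi-view weighting only;
    ``None`` selects a data-driven scale at fit time).  ``eta`` is the
    collaboration strength of CoFKM, valid in ``[0, (V-1)/V]``.
    ``weight_init`` selects the view-weight initialization: "diagonal"
    (default), "uniform" or "random".
    """

    n_clusters: int = 4
    fuzzifier: float = 2.0
    tol: float = 1e-3
    max_iter: int = 100
    seed: Optional[int] = None
    gamma: Optional[float] = None
    eta: float = 0.0
    weight_init: str = "diagonal"

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.weight_init not in ("diagonal", "uniform", "random"):
            raise ValueError(f"unknown weight_init {self.weight_init!r}")


@dataclass
class SegmentationResult:
    """Everything a fit produces.

    ``fused_membership`` is the final fused partition; ``labels`` its
    per-sample argmax.  ``per_view_membership`` holds the V per-view
    partitions, ``weights`` the final view-weight matrix (``None`` for
    algorithms without one).  ``objective_trace`` records the objective after
    every full iteration.
    """

    fused_membership: MembershipMatrix
    labels: np.ndarray
    per_view_membership: list[MembershipMatrix]
    centers: ClusterCenters
    weights: Optional[ViewWeightMatrix]
    objective_trace: list[float]
    converged: bool
    n_iter: int
    params: dict = field(default_factory=dict)

    def label_map(self) -> np.ndarray:
        """Reshape labels to the (H, W) pixel grid recorded at build time."""
        shape = self.params.get("sample_shape")
        if shape is None:
            raise ValueError("no sample_shape recorded; data was not an image")
        return self.labels.reshape(shape)
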