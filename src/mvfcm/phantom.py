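"""Synthetic data: brain-like phantoms and multi-view Gaussian mixtures.

The image phantom emulates a T1-weighted axial slice with four classes —
background, CSF, GM, WM — as nested smooth regions: an elliptical head whose
outer ribbon is CSF, a folded GM band, a WM interior, and two CSF ventricle
blobs.  Each pixel's clean intensity is exactly its class mean (default 8-bit
scale: 0 / 70 / 130 / 200, the dark-to-bright CSF < GM < WM ordering of
T1-weighted contrast), so the noise-free histogram has exactly four values.
Additive Gaussian noise at x% of the full intensity range (clipped to the
valid range) provides the robustness benchmark conditions.

The tabular generator draws multi-view Gaussian mixtures, optionally with
class-independent pure-noise views, for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import MultiViewData

__all__ = [
    "PhantomSpec",
    "MixtureSpec",
    "generate_phantom",
    "add_gaussian_noise",
    "generate_mixture_mvd",
    "CLASS_NAMES",
]

CLASS_NAMES = ("background", "CSF", "GM", "WM")


@dataclass
class PhantomSpec:
    size: tuple[int, int] = (128, 128)
    class_means: tuple[float, float, float, float] = (0.0, 70.0, 130.0, 200.0)
    noise_percent: float = 0.0
    geometry_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.class_means)) != len(self.class_means):
            raise ValueError("class means must be distinct")
        if self.noise_percent < 0:
            raise ValueError("noise_percent must be >= 0")


def add_gaussian_noise(image, percent: float, seed: Optional[int] = None,
                       value_range: Optional[float] = None) -> np.ndarray:
    """Add zero-mean Gaussian noise with sigma = percent/100 of the intensity range.

    ``value_range`` defaults to 255 for 8-bit-scale images and 1.0 for
    normalized ones; output is clipped to [0, value_range].
    """
    if percent < 0:
        raise ValueError("noise percent must be >= 0")
    img = np.asarray(image, dtype=float)
    if value_range is None:
        value_range = 255.0 if img.max() > 1.5 else 1.0
    if percent == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    sigma = percent / 100.0 * value_range
    noisy = img + rng.normal(0.0, sigma, size=img.shape)
    return np.clip(noisy, 0.0, value_range)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build a phantom slice; returns (image, label map), both (H, W).

    Labels: 0 background, 1 CSF, 2 GM, 3 WM.  Region boundaries are low-order
    sinusoidal perturbations of nested ellipses whose phases come from
    ``geometry_seed``; noise (if any) uses ``seed``.  Deterministic given both.
    """
    h, w = spec.size
    if h < 32 or w < 32:
        raise ValueError(f"phantom size {spec.size} too small; need >= 32x32")
    grng = np.random.default_rng(spec.geometry_seed)
    phases = grng.uniform(0.0, 2.0 * np.pi, size=4)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / (0.42 * h), (xx - cx) / (0.36 * w)
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    head = 1.0 + 0.04 * np.sin(3 * theta + phases[0]) \
               + 0.03 * np.sin(5 * theta + phases[1])
    gm_outer = head - 0.08  # CSF ribbon just inside the head boundary
    wm = 0.62 * (1.0 + 0.10 * np.sin(6 * theta + phases[2])
                 + 0.06 * np.sin(9 * theta + phases[3]))

    labels = np.zeros((h, w), dtype=int)
    labels[rho <= head] = 1
    labels[rho <= gm_outer] = 2
    labels[rho <= wm] = 3

    # two CSF ventricle blobs inside WM, jittered by the geometry seed
    jit = grng.uniform(-0.01, 0.01, size=4)
    for sign, jy, jx in ((-1, jit[0], jit[1]), (1, jit[2], jit[3])):
        vy = cy + (0.04 + jy) * h
        vx = cx + sign * (0.10 + jx) * w
        vent = (((yy - vy) / (0.10 * h)) ** 2
                + ((xx - vx) / (0.045 * w)) ** 2) <= 1.0
        labels[vent & (labels == 3)] = 1

    image = np.asarray(spec.class_means, dtype=float)[labels]
    if spec.noise_percent > 0:
        value_range = max(255.0, float(max(spec.class_means)))
        image = add_gaussian_noise(image, spec.noise_percent, seed=spec.seed,
                                   value_range=value_range)
    return image, labels


@dataclass
class MixtureSpec:
    """Multi-view Gaussian-mixture fixture.

    Informative views share the latent class per sample; ``means`` may be
    given explicitly (one (C, p_v) array per informative view) or generated as
    1-D views with cluster means spaced ``separation * sd`` apart.  Pure-noise
    views draw from a single class-independent Gaussian.  With ``standardize``
    (the default) every view dimension is z-scored after generation so the
    views are scale-commensurate, matching the convention of the image
    feature views; cluster separation in within-class standard deviations is
    unchanged by this.
    """

    n_samples: int = 300
    n_views: int = 2
    n_clusters: int = 3
    separation: float = 5.0
    sd: float = 1.0
    n_noise_views: int = 0
    noise_sd: float = 1.0
    proportions: Optional[Sequence[float]] = None
    means: Optional[Sequence[np.ndarray]] = None
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_samples:
            raise ValueError("n_clusters exceeds n_samples")
        if self.sd <= 0 or self.noise_sd <= 0:
            raise ValueError("standard deviations must be > 0")
        if self.n_views < 1 or self.n_noise_views < 0:
            raise ValueError("invalid view counts")
        if self.proportions is not None:
            p = np.asarray(self.proportions, dtype=float)
            if p.shape != (self.n_clusters,) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
                raise ValueError("proportions must be a distribution over clusters")


def generate_mixture_mvd(spec: MixtureSpec) -> tuple[MultiViewData, np.ndarray]:
    """Draw (MultiViewData, true labels); deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    c = spec.n_clusters
    p = (np.full(c, 1.0 / c) if spec.proportions is None
         else np.asarray(spec.proportions, dtype=float))
    labels = rng.choice(c, size=spec.n_samples, p=p)

    if spec.means is None:
        means = [np.arange(c, dtype=float)[:, None] * spec.separation * spec.sd
                 for _ in range(spec.n_views)]
    else:
        means = [np.atleast_2d(np.asarray(mu, dtype=float)) for mu in spec.means]
        if len(means) != spec.n_views:
            raise ValueError("need one mean matrix per informative view")

    views = []
    for mu in means:
        views.append(mu[labels] + spec.sd * rng.standard_normal((spec.n_samples, mu.shape[1])))
    for _ in range(spec.n_noise_views):
        views.append(spec.noise_sd * rng.standard_normal((spec.n_samples, 1)))
    if spec.standardize:
        views = [(v - v.mean(axis=0)) / np.where(v.std(axis=0) > 0, v.std(axis=0), 1.0)
                 for v in views]
    return MultiViewData(views=views), labels
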