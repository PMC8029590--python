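"""Dense per-pixel feature views for image clustering.

A grayscale image becomes multi-view data by computing one feature map per
view and flattening it row-major: raw intensity, dense HOG (unsigned
orientation histogram), local Shannon entropy, Sobel gradient magnitude, and
local contrast (window range).  Windowed features use reflect padding.  Every
view is z-scored per dimension before clustering so that Euclidean distances
are commensurate across views.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import MultiViewData

__all__ = [
    "Image2D",
    "ViewSpec",
    "default_view_specs",
    "intensity_view",
    "gradient_view",
    "entropy_view",
    "contrast_view",
    "hog_view",
    "build_multiview",
    "median_denoise",
]

FEATURES = ("intensity", "hog", "entropy", "gradient", "contrast")


@dataclass
class Image2D:
    """A 2-D grayscale image; pixel (r, c) is sample r * W + c."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
        if arr.shape[0] < 3 or arr.shape[1] < 3:
            raise ValueError(
                f"image {arr.shape} too small; feature windows need >= 3x3")
        if not np.isfinite(arr).all():
            raise ValueError("image contains non-finite pixels")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ViewSpec:
    """One feature view: name, window radius, HOG bin count, on/off flag."""

    feature: str
    radius: int = 3
    bins: int = 9
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(
                f"unknown feature {self.feature!r}; choose from {FEATURES}")
        if self.radius < 1:
            raise ValueError("window radius must be >= 1")
        if self.bins < 2:
            raise ValueError("HOG needs at least 2 orientation bins")


def default_view_specs(radius: int = 3, include_intensity: bool = True) -> list[ViewSpec]:
    """Intensity (optional) plus the four texture views at one window radius."""
    specs = []
    if include_intensity:
        specs.append(ViewSpec("intensity", radius))
    specs += [ViewSpec("hog", radius), ViewSpec("entropy", radius),
              ViewSpec("gradient", radius), ViewSpec("contrast", radius)]
    return specs


def _image(image) -> np.ndarray:
    if isinstance(image, Image2D):
        return image.pixels
    return Image2D(image).pixels


def intensity_view(image) -> np.ndarray:
    """Raw gray values, one column."""
    return _image(image).reshape(-1, 1)


def _sobel_xy(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return gx, gy


def gradient_view(image) -> np.ndarray:
    """Per-pixel Sobel gradient magnitude sqrt(Gx^2 + Gy^2), one column."""
    gx, gy = _sobel_xy(_image(image))
    return np.hypot(gx, gy).reshape(-1, 1)


def _quantize_256(img: np.ndarray) -> np.ndarray:
    # 256 gray levels for the window histogram; [0,1] floats are scaled up
    if img.max() <= 1.0:
        img = img * 255.0
    return np.clip(np.rint(img), 0, 255).astype(np.intp)


def entropy_view(image, window_radius: int = 3) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of the windowed 256-level histogram."""
    img = _image(image)
    q = _quantize_256(img)
    r = window_radius
    k = 2 * r + 1
    padded = np.pad(q, r, mode="reflect")
    wins = np.lib.stride_tricks.sliding_window_view(padded, (k, k))
    wins = wins.reshape(-1, k * k)
    n = wins.shape[0]
    out = np.empty(n)
    area = float(k * k)
    chunk = 8192
    for start in range(0, n, chunk):
        block = wins[start:start + chunk]
        rows = np.arange(block.shape[0])[:, None]
        counts = np.bincount((rows * 256 + block).ravel(),
                             minlength=block.shape[0] * 256)
        counts = counts.reshape(block.shape[0], 256)
        p = counts / area
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        out[start:start + chunk] = -terms.sum(axis=1)
    return out.reshape(-1, 1)


def contrast_view(image, window_radius: int = 3) -> np.ndarray:
    """Per-pixel local contrast: window max minus window min."""
    img = _image(image)
    k = 2 * window_radius + 1
    hi = ndimage.maximum_filter(img, size=k, mode="reflect")
    lo = ndimage.minimum_filter(img, size=k, mode="reflect")
    return (hi - lo).reshape(-1, 1)


def hog_view(image, window_radius: int = 3, n_bins: int = 9) -> np.ndarray:
    """Dense HOG: per-pixel magnitude-weighted unsigned-orientation histogram.

    Orientations live in [0, 180) degrees split into ``n_bins`` equal bins;
    each pixel's descriptor sums gradient magnitude per bin over its window
    and is L2-normalized (all-zero descriptors are left at zero).
    """
    img = _image(image)
    gx, gy = _sobel_xy(img)
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    bin_idx = np.minimum((ang / (180.0 / n_bins)).astype(int), n_bins - 1)
    k = 2 * window_radius + 1
    hist = np.empty(img.shape + (n_bins,))
    for b in range(n_bins):
        contrib = np.where(bin_idx == b, mag, 0.0)
        hist[..., b] = ndimage.uniform_filter(contrib, size=k,
                                              mode="reflect") * (k * k)
    # uniform_filter round-off can leave ~-1e-18 in flat areas; histograms
    # are non-negative by construction
    desc = np.maximum(hist.reshape(-1, n_bins), 0.0)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    return np.where(norms > 0, desc / np.where(norms > 0, norms, 1.0), 0.0)


def median_denoise(image, size: int = 3) -> Image2D:
    """Optional 3x3 median prefilter (off by default in the pipeline)."""
    return Image2D(ndimage.median_filter(_image(image), size=size))


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = x - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0  # zero-variance dimensions carry no signal
    return out


def build_multiview(image, view_specs: Optional[Sequence[ViewSpec]] = None,
                    zscore: bool = True) -> MultiViewData:
    """Assemble enabled feature views into z-scored multi-view data."""
    img = _image(image)
    if view_specs is None:
        view_specs = default_view_specs()
    views = []
    for spec in view_specs:
        if not spec.enabled:
            continue
        if spec.feature == "intensity":
            f = intensity_view(img)
        elif spec.feature == "hog":
            f = hog_view(img, spec.radius, spec.bins)
        elif spec.feature == "entropy":
            f = entropy_view(img, spec.radius)
        elif spec.feature == "gradient":
            f = gradient_view(img)
        else:
            f = contrast_view(img, spec.radius)
        views.append(_zscore_columns(f) if zscore else f)
    if not views:
        raise ValueError("no enabled views")
    return MultiViewData(views=views, sample_shape=img.shape)
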