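"""End-to-end segmentation pipeline and experiment harnesses.

Flow: (optional denoise) -> build feature views -> cluster -> fuse -> label
map -> validity metrics.  The single-view FCM baseline clusters the raw
intensity view only; the multi-view algorithms consume the constructed views,
reproducing the single- vs multi-view comparison design.  Harnesses: an
exhaustive grid search over named parameter grids and a noise-robustness
experiment over phantom replicates.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cofkm import cofkm_fit
from .core import FitConfig, MultiViewData, SegmentationResult
from .fcm import fcm_fit
from .imvfcm import imv_fit
from .metrics import partition_coefficient, partition_entropy, tissue_report
from .phantom import CLASS_NAMES, PhantomSpec, add_gaussian_noise, generate_phantom
from .views import Image2D, ViewSpec, build_multiview, default_view_specs, median_denoise

__all__ = [
    "ALGORITHMS",
    "segment_image",
    "grid_search",
    "noise_experiment",
    "degradation_summary",
    "plot_degradation",
    "write_manifest",
]

log = logging.getLogger(__name__)

ALGORITHMS = ("fcm", "cofkm", "imvfcm")

_GRID_KEYS = {"m": "fuzzifier", "fuzzifier": "fuzzifier", "gamma": "gamma",
              "eta": "eta", "n_clusters": "n_clusters"}


def _fit(data: MultiViewData, algorithm: str, config: FitConfig) -> SegmentationResult:
    if algorithm == "fcm":
        return fcm_fit(data, config)
    if algorithm == "cofkm":
        return cofkm_fit(data, config)
    if algorithm == "imvfcm":
        return imv_fit(data, config)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _views_for(image, algorithm: str,
               view_specs: Optional[Sequence[ViewSpec]]) -> MultiViewData:
    if view_specs is None:
        # FCM follows the classic single-view flow on gray values alone
        view_specs = ([ViewSpec("intensity")] if algorithm == "fcm"
                      else default_view_specs())
    return build_multiview(image, view_specs)


def segment_image(image, algorithm: str = "imvfcm",
                  view_specs: Optional[Sequence[ViewSpec]] = None,
                  config: Optional[FitConfig] = None,
                  reference_labels=None,
                  denoise: bool = False) -> tuple[SegmentationResult, dict]:
    """Segment one image; returns the fit result and a metrics report.

    The report always carries the label map and the reference-free V_pc/V_pe
    of the fused partition; with ``reference_labels`` it adds per-class and
    mean-tissue JS/DSC/ME after label alignment.
    """
    img = image if isinstance(image, Image2D) else Image2D(np.asarray(image, dtype=float))
    if denoise:
        img = median_denoise(img)
    data = _views_for(img, algorithm, view_specs)
    if config is None:
        config = FitConfig(n_clusters=4)
    result = _fit(data, algorithm, config)
    fused = result.fused_membership.values
    report = {
        "algorithm": algorithm,
        "n_clusters": config.n_clusters,
        "label_map": result.labels.reshape(img.shape),
        "v_pc": partition_coefficient(fused),
        "v_pe": partition_entropy(fused),
        "converged": result.converged,
        "n_iter": result.n_iter,
    }
    if reference_labels is not None:
        ref = np.asarray(reference_labels).ravel()
        if ref.size != data.n_samples:
            raise ValueError(
                f"reference has {ref.size} labels, image has {data.n_samples} pixels")
        names = CLASS_NAMES if config.n_clusters == 4 else None
        report.update(tissue_report(result.labels, ref, config.n_clusters,
                                    background_label=0, class_names=names))
    return result, report


def grid_search(image, algorithm: str, grids: dict,
                view_specs: Optional[Sequence[ViewSpec]] = None,
                base_config: Optional[FitConfig] = None,
                reference_labels=None,
                denoise: bool = False) -> tuple[FitConfig, pd.DataFrame]:
    """Exhaustive search over named parameter grids.

    With reference labels the selection score is the mean tissue JS; without,
    the partition coefficient V_pc of the fused partition.  Ties break toward
    the earlier grid point, so the result is deterministic.
    """
    if not grids:
        raise ValueError("grids must be non-empty")
    unknown = set(grids) - set(_GRID_KEYS)
    if unknown:
        raise ValueError(f"unknown grid parameter(s): {sorted(unknown)}")
    if base_config is None:
        base_config = FitConfig(n_clusters=4)
    names = list(grids)
    rows = []
    best = None
    for combo in itertools.product(*(grids[k] for k in names)):
        cfg = replace(base_config,
                      **{_GRID_KEYS[k]: v for k, v in zip(names, combo)})
        _, report = segment_image(image, algorithm, view_specs, cfg,
                                  reference_labels, denoise)
        score = (report["mean"]["js"] if reference_labels is not None
                 else report["v_pc"])
        row = dict(zip(names, combo))
        row.update(score=score, v_pc=report["v_pc"], v_pe=report["v_pe"])
        if reference_labels is not None:
            row["mean_js"] = report["mean"]["js"]
            row["mean_dsc"] = report["mean"]["dsc"]
        rows.append(row)
        if best is None or score > best[0]:
            best = (score, cfg)
    return best[1], pd.DataFrame(rows)


def _derived_seed(base: int, *parts: int) -> int:
    s = int(base)
    for p in parts:
        s = (s * 1000003 + int(p) * 8191 + 1) % (2 ** 31)
    return s


def noise_experiment(phantom_spec: Optional[PhantomSpec] = None,
                     noise_levels: Sequence[float] = (0, 3, 5, 7, 9),
                     algorithms: Sequence[str] = ("fcm", "imvfcm"),
                     n_seeds: int = 10,
                     base_seed: int = 0,
                     config: Optional[FitConfig] = None,
                     view_specs: Optional[Sequence[ViewSpec]] = None) -> pd.DataFrame:
    """Noise-robustness benchmark on phantom replicates.

    For each seed a fresh phantom geometry is drawn; each noise level corrupts
    the same clean image, and each algorithm segments it against the known
    labels.  Returns one row per (algorithm, level, seed) with the mean tissue
    JS and DSC.  The level list must contain 0 (the degradation baseline).
    """
    levels = sorted(float(x) for x in noise_levels)
    if 0.0 not in levels:
        raise ValueError("noise_levels must include 0 for baselining")
    if phantom_spec is None:
        phantom_spec = PhantomSpec()
    if config is None:
        config = FitConfig(n_clusters=4)
    rows = []
    for s in range(n_seeds):
        spec = replace(phantom_spec, noise_percent=0.0,
                       geometry_seed=_derived_seed(base_seed, s, 1))
        clean, labels = generate_phantom(spec)
        vrange = max(255.0, float(max(spec.class_means)))
        for level in levels:
            img = add_gaussian_noise(clean, level,
                                     seed=_derived_seed(base_seed, s, 2, int(level * 10)),
                                     value_range=vrange)
            for alg in algorithms:
                cfg = replace(config, seed=_derived_seed(base_seed, s, 3, int(level * 10)))
                _, report = segment_image(img, alg, view_specs, cfg,
                                          reference_labels=labels)
                rows.append({"algorithm": alg, "noise_percent": level,
                             "seed": s, "mean_js": report["mean"]["js"],
                             "mean_dsc": report["mean"]["dsc"]})
                log.info("noise-exp %s level=%g seed=%d JS=%.4f",
                         alg, level, s, rows[-1]["mean_js"])
    return pd.DataFrame(rows)


def degradation_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Seed-averaged JS/DSC per algorithm and level, with drop rates vs 0%.

    Drop rate is ``100 * (1 - score/score_at_0)`` in percent; the 0% row has
    drop rate 0 by definition.
    """
    summary = (results.groupby(["algorithm", "noise_percent"], as_index=False)
               [["mean_js", "mean_dsc"]].mean())
    out = []
    for alg, grp in summary.groupby("algorithm"):
        grp = grp.sort_values("noise_percent").copy()
        base = grp.loc[grp["noise_percent"] == 0.0]
        for col in ("mean_js", "mean_dsc"):
            b = float(base[col].iloc[0])
            grp[f"{col}_drop_pct"] = 100.0 * (1.0 - grp[col] / b)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def plot_degradation(summary: pd.DataFrame, path) -> None:
    """Write a JS-vs-noise degradation plot (one line per algorithm)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for alg, grp in summary.groupby("algorithm"):
        grp = grp.sort_values("noise_percent")
        ax.plot(grp["noise_percent"], 100 * grp["mean_js"], marker="o", label=alg)
    ax.set_xlabel("Gaussian noise level (%)")
    ax.set_ylabel("mean tissue JS (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_manifest(path, **entries) -> None:
    """Dump a reproducibility manifest (all parameters and seeds) as JSON."""
    def _clean(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, FitConfig):
            return asdict(obj)
        if isinstance(obj, PhantomSpec):
            return asdict(obj)
        if isinstance(obj, ViewSpec):
            return asdict(obj)
        if isinstance(obj, (list, tuple)):
            return [_clean(x) for x in obj]
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        return obj
    Path(path).write_text(json.dumps(_clean(entries), indent=2, default=str))
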