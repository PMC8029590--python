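"""Image input/output: 8-bit grayscale PNG and single NIfTI slices."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["load_image", "load_labels", "save_gray_png", "save_label_png"]


def load_image(path, nifti_axis: int = 2,
               nifti_index: Optional[int] = None) -> np.ndarray:
    """Read a 2-D grayscale image from PNG or a single slice from NIfTI.

    For NIfTI volumes the slice is taken along ``nifti_axis`` at
    ``nifti_index`` (defaults to the middle slice).
    """
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib
        vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
        if vol.ndim == 2:
            return vol
        if vol.ndim != 3:
            raise ValueError(f"expected a 2-D/3-D NIfTI, got ndim={vol.ndim}")
        if nifti_index is None:
            nifti_index = vol.shape[nifti_axis] // 2
        return np.take(vol, nifti_index, axis=nifti_axis)
    from PIL import Image
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def load_labels(path, **kwargs) -> np.ndarray:
    """Read a label mask; distinct gray values map to labels 0..C-1."""
    arr = load_image(path, **kwargs)
    values = np.unique(arr)
    lut = {v: i for i, v in enumerate(values)}
    return np.vectorize(lut.get)(arr).astype(int)


def save_gray_png(image: np.ndarray, path) -> None:
    from PIL import Image
    arr = np.clip(np.asarray(image, dtype=float), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def save_label_png(labels: np.ndarray, path, n_classes: Optional[int] = None) -> None:
    """Save a label map as 8-bit PNG with classes spread over 0..255."""
    from PIL import Image
    lab = np.asarray(labels, dtype=int)
    c = n_classes if n_classes is not None else int(lab.max()) + 1
    scale = 255 // max(c - 1, 1)
    Image.fromarray((lab * scale).astype(np.uint8), mode="L").save(str(path))
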