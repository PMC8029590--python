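"""Build the multi-view representation of an image.

Turns one grayscale image into five feature views — raw intensity, dense HOG,
local entropy, Sobel gradient magnitude and local contrast — each z-scored per
dimension, and prints their shapes and the per-view feature ranges before
scaling.  Every pixel becomes one sample observed in all views.
"""

import numpy as np

from mvfcm import PhantomSpec, generate_phantom
from mvfcm.views import (build_multiview, contrast_view, default_view_specs,
                         entropy_view, gradient_view, hog_view)

image, _ = generate_phantom(PhantomSpec(size=(64, 64)))

data = build_multiview(image, default_view_specs(radius=3))
print(f"{data.n_views} views, N={data.n_samples} pixel samples, "
      f"dims={data.view_dims}, sample grid {data.sample_shape}")

raw = {
    "hog": hog_view(image, 3),
    "entropy": entropy_view(image, 3),
    "gradient": gradient_view(image),
    "contrast": contrast_view(image, 3),
}
for name, feat in raw.items():
    print(f"  {name:>8}: shape {feat.shape}, "
          f"range [{feat.min():.2f}, {feat.max():.2f}]")
print("Entropy is in bits over a 7x7 window; contrast is the window range in "
      "gray levels; gradient is Sobel magnitude.")
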