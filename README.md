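# mvfcm

Multi-view fuzzy c-means clustering with adaptive, entropy-regularized view
weights, built for brain MRI tissue segmentation experiments: separating white
matter (WM), gray matter (GM) and cerebrospinal fluid (CSF) from a background
cluster in 2-D slices.

MRI tissue boundaries are ambiguous (partial-volume effects, noise, bias
fields), which is why fuzzy partitions — every pixel gets a *degree* of
membership in every tissue — are the standard tool for this task.  The package
provides:

- **`mvfcm.fcm`** — the classic single-view fuzzy c-means baseline;
- **`mvfcm.cofkm`** — collaborative multi-view fuzzy k-means (per-view
  partitions coupled at strength η, fused by an elementwise geometric mean);
- **`mvfcm.imvfcm`** — the adaptive-weight multi-view model (below);
- **`mvfcm.views`** — turns a grayscale image into multi-view data: raw
  intensity plus dense HOG, local entropy, Sobel gradient magnitude and local
  contrast, one feature map per view, pixels as samples;
- **`mvfcm.metrics`** — Jaccard (JS), Dice (DSC), kappa index (KI), partition
  coefficient (V_pc), partition entropy (V_pe), misclassification error (ME),
  and optimal cluster-to-class alignment;
- **`mvfcm.phantom`** — synthetic four-class brain phantoms with Gaussian
  noise, and multi-view Gaussian-mixture generators for controlled recovery
  experiments;
- **`mvfcm.pipeline`** + a thin `mvfcm` CLI — image → views → clustering →
  label map → metrics, plus grid-search and noise-robustness harnesses.

## The model

For `N` samples seen in `V` views (view `v` with its own dimension), the
adaptive-weight model keeps one fuzzy partition `U_t = [u_{ij,t}]` (C × N,
columns on the simplex) per view, per-view centers `z_{i,v}`, and a V × V
row-stochastic weight matrix `W = [w_{v,t}]`, minimizing

```
J = Σ_v Σ_i Σ_j Σ_t  w_{v,t} · u_{ij,t}^m · ‖x_{j,v} − z_{i,v}‖²
    + γ Σ_v Σ_t w_{v,t} log w_{v,t}
```

subject to `Σ_i u_{ij,t} = 1` and `Σ_t w_{v,t} = 1`.  `m > 1` is the
fuzzifier (default 2), and `γ > 0` is the temperature of the entropy
regularizer.  Each block update is closed-form and exactly optimal:

- centers: weighted means with weights `Σ_t w_{v,t} u_{ij,t}^m`;
- memberships: inverse-distance allocation under the aggregated metric
  `D_t(i,j) = Σ_v w_{v,t} d²_{ij,v}` with exponent `1/(m−1)`;
- weights: row-wise softmax `w_{v,t} ∝ exp(−S_{v,t}/γ)` over the scatter
  `S_{v,t} = Σ_{ij} u_{ij,t}^m d²_{ij,v}` (how badly partition `t` fits view
  `v`'s geometry).

So `J` is non-increasing across iterations; the loop stops when
`|J_{l+1} − J_l| < ε` (default 0.001) or after `l = 100` iterations.  The
final partition is the weighted average `Ū = Σ_t a_t U_t` with
`a_t = (1/V) Σ_v w_{v,t}`, and crisp labels are its per-pixel argmax.  Large
γ flattens `W` toward uniform (consensus clustering); small γ concentrates
each row on the best-fitting partition (decoupled per-view clustering).

## Worked example

`python examples/segment_phantom.py` builds a 128×128 phantom (four classes
with exact gray levels 0/70/130/200), adds 5% Gaussian noise (σ = 5% of the
255 intensity range), and segments it two ways:

```
fcm (V_pc=0.921, V_pe=0.173, 12 iterations)
  background: JS=0.997 DSC=0.999
         CSF: JS=0.961 DSC=0.980
          GM: JS=0.980 DSC=0.990
          WM: JS=0.989 DSC=0.995
  tissue mean: JS=0.977 DSC=0.988

imvfcm (V_pc=0.385, V_pe=1.144, 31 iterations)
  background: JS=0.643 DSC=0.782
         CSF: JS=0.002 DSC=0.004
          GM: JS=0.663 DSC=0.798
          WM: JS=0.963 DSC=0.981
  tissue mean: JS=0.543 DSC=0.594
```

Each JS/DSC row compares one aligned cluster with the known tissue mask (1 is
a perfect match); the tissue mean averages WM/GM/CSF and excludes background.
On this piecewise-constant phantom, intensity alone separates the four classes
almost perfectly, while the texture views (HOG, entropy, gradient, contrast)
encode *boundary geometry* rather than tissue identity — so the multi-view
run spends clusters on boundary structure and scores lower.  See
`docs/methods.md` for why this is a property of the phantom, and what the
mixture experiments (`examples/view_weights.py`, where all views share one
cluster structure) show instead.

Other examples: `examples/feature_views.py` (view construction),
`examples/noise_robustness.py` (degradation curves),
`examples/view_weights.py` (the learned weight matrix on mixture data with a
pure-noise view).

The CLI mirrors the pipeline:

```
mvfcm phantom --size 128 --noise 5 --seed 1 --out-dir out/ph
mvfcm segment --image out/ph/phantom.png --labels out/ph/labels.png \
      --algorithm imvfcm -C 4 --seed 0 --out-dir out/seg
mvfcm noise-exp --levels 0,3,5,7,9 --n-seeds 10 --out-dir out/noise
```

Every run writes a JSON manifest with all parameters and seeds.

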