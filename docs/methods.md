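# Methods

This note documents the models implemented in `mvfcm`, the choices made where
the design was genuinely open, what the synthetic generators do and do not
emulate, and the known limitations.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Models

### Single-view fuzzy c-means (`mvfcm.fcm`)

FCM minimizes `J = Σ_i Σ_j u_ij^m d²(x_j, z_i)` over column-stochastic
memberships and free centers by exact alternating minimization: centers are
`u^m`-weighted means; memberships follow the inverse-distance closed form with
exponent `1/(m−1)`.  Both half-steps are the exact block minimizers, so the
objective trace is non-increasing (asserted in tests with 1e-10 slack; the
membership closed form is additionally cross-checked against an SLSQP
simplex-constrained minimizer on random instances).

### Collaborative multi-view fuzzy k-means (`mvfcm.cofkm`)

Each view keeps its own partition; view `v`'s objective contribution weighs
its squared distances by the fused coefficient
`ũ_{ij,v} = (1−η) u_{ij,v}^m + η/(V−1) Σ_{v'≠v} u_{ij,v'}^m`, with the
coupling strength `η ∈ [0, (V−1)/V]`.  At `η = 0` the fit is exactly `V`
independent FCM runs (asserted to 1e-8).  The printed membership update of
this family is the `m = 2` instantiation; for other `m` we generalize with the
`1/(m−1)` exponent, consistent with the single-view form, and log that the
generalized rule is in use.  Monotone descent of the coupled objective is not
guaranteed and is logged rather than asserted.  The final partition is the
elementwise geometric mean of the per-view partitions; that mean is not
column-stochastic, so we renormalize columns for validity indices while taking
crisp labels from the raw fusion (argmax is invariant to positive column
rescaling; a column whose every cluster hits an absorbing zero falls back to
the arithmetic mean of the views).

### Adaptive-weight multi-view FCM (`mvfcm.imvfcm`)

The objective, constraints and block updates are stated in the README.  Key
numerical and design points:

- **Update order** per iteration: centers → memberships → weights, then the
  objective is recorded.  Each update is the exact constrained minimizer of
  its block (verified against numerical optimizers in the acceptance tests),
  so the trace is non-increasing up to round-off.
- **Weight softmax** is computed with row-max subtraction; results are
  invariant to per-row shifts of the scatter matrix and safe for
  `S/γ` up to overflow scale.
- **Zero aggregated distance**: a sample at distance zero from one or more
  centers takes full membership, split equally among the zero-distance
  clusters — the analytic limit of the closed form.  The same rule handles
  inverse-power overflow for astronomically small distances.
- **Degenerate clusters**: a cluster whose total membership weight reaches
  zero is re-seeded on the sample with the lowest best-membership, keeping C
  fixed.  A re-seed can break monotonicity for that iteration; it never
  triggered in the seeded test conditions.
- **Initialization**: memberships are random column-stochastic
  (Dirichlet(1,…,1) per column, seeded).  The weight matrix defaults to the
  deterministic diagonal-dominant blend `W0 = 0.5·I + 0.5/V · J` rather than
  the uniform matrix: uniform `W0` has identical columns, so after one
  membership update every per-view partition collapses onto the same matrix,
  the scatter `S_{v,t}` becomes constant in `t`, and the weight update returns
  the uniform matrix forever — the adaptive mechanism would be inert from the
  start.  Anchoring partition `t` to view `t` gives the weights something to
  adapt to while keeping runs reproducible without extra RNG draws; `uniform`
  and seeded `random` schemes remain available.
- **Temperature γ**: with `gamma=None` (the default) the fit sets
  `γ = mean_v (max_t S_{v,t} − min_t S_{v,t})` at the first weight update —
  the softmax argument spread is then of order one, adaptive but not
  winner-take-all — and keeps it fixed so the objective is well defined.  The
  resolved value is recorded in `result.params["gamma"]`.  The grid-search
  harness exposes the conventional `{2^-12, …, 2^12}` grid; without reference
  labels the selection score is the partition coefficient V_pc of the fused
  partition, with labels the mean tissue JS.
- **Ensemble**: `Ū = Σ_t a_t U_t` with `a_t = (1/V) Σ_v w_{v,t}` (the
  denominator `Σ_t Σ_v w_{v,t}` equals V by row-stochasticity), crisp labels
  by per-column argmax.  Centers are reported per view; no fused center is
  defined by the model.

**Weight dynamics worth knowing.**  The coupled updates have two stable
regimes: a *consensus* regime (larger γ) where all per-view partitions merge
and `W` is exactly uniform, and a *decoupled* regime (small γ) where `W`
approaches the identity and every view overfits its own partition.  In both,
the ensemble coefficients `a_t` are uniform — the identity's column means are
also `1/V`.  Down-weighting of an uninformative view's partition is therefore
a *transient* of the adaptation visible in mid-iteration weight matrices, not
a property of the converged state; `examples/view_weights.py` prints a
converged `W` so this is easy to inspect.  Consequently the model's benefit
shows up when the informative views agree on one cluster structure (the
mixture recovery experiments), not as a persistent weight signature.

## Image feature views (`mvfcm.views`)

The four texture features have no canonical dense definition, so we fix
standard ones, all reflect-padded and recorded in `ViewSpec` so alternates can
be swapped:

- **gradient**: 3×3 Sobel magnitude `√(Gx² + Gy²)`;
- **entropy**: Shannon entropy (bits) of the 256-level gray histogram in a
  `(2r+1)²` window;
- **contrast**: window max − min;
- **HOG**: per-pixel gradient-magnitude-weighted histogram of unsigned
  orientation (`[0°, 180°)`, 9 bins by default, hard assignment), summed over
  the window and L2-normalized (zero descriptors stay zero).

Default window radius is 3 (7×7): large enough for stable statistics at the
128–256 px image scale.  Raw intensity is included as a fifth view by default —
the texture features are locally flat inside homogeneous tissue, so the
clustering must see gray levels to separate tissues at all.  Every view is
z-scored per dimension before clustering (distances across views are otherwise
scale-incommensurate); zero-variance dimensions are set to 0.  An optional 3×3
median prefilter is available and off by default.  Pixels map to samples
row-major: `(r, c) → r·W + c`.

## Validity metrics (`mvfcm.metrics`)

JS, DSC, KI and ME follow their standard set-overlap definitions; DSC ≡ KI ≡
`2·JS/(1+JS)` are exact identities asserted in tests.  ME is asymmetric (it
normalizes by the gold-standard area).  The partition entropy is the standard
Bezdek form `V_pe = −(1/n) Σ u ln u` (natural log, `0·ln 0 = 0`), bounded by
`[0, ln C]`; V_pc lies in `[1/C, 1]`.  Cluster indices are arbitrary, so
per-tissue scoring first aligns clusters to classes by maximum-overlap
assignment on the contingency table (`scipy.optimize.linear_sum_assignment`);
the summary "tissue mean" averages the non-background classes only.

## Synthetic generators (`mvfcm.phantom`)

**Image phantom.**  Four classes — background, CSF, GM, WM — as nested smooth
regions: an elliptical head whose boundary and internal interfaces are
low-order sinusoidal perturbations (phases from `geometry_seed`), a CSF ribbon
inside the skull line, a folded GM band, a WM interior and two CSF ventricle
blobs.  Class gray levels default to 0/70/130/200 on the 8-bit scale —
the dark-to-bright CSF < GM < WM ordering of T1-weighted contrast; the exact
values are fixture choices.  Every pixel's clean intensity is exactly its
class mean, so the noise-free histogram has exactly four values and FCM can
recover the class means to within one gray level (tested).  "x% Gaussian
noise" adds zero-mean noise with σ = x% of the full intensity range, clipped
to the valid range afterwards; clipping slightly truncates tails at the 7–9%
levels.  At the default 128×128 geometry every class covers at least 2% of
pixels.

What the phantom does **not** emulate: within-tissue texture, partial-volume
mixing at boundaries, bias fields, and Rician noise.  This matters for
interpreting multi-view results: on piecewise-constant regions the texture
views respond to *boundaries*, not tissue identity, so they share no cluster
structure with intensity, and multi-view clustering of this phantom scores
below intensity-only FCM (the README example shows the measured gap).  Passing
tests on the phantom therefore validate the mechanics of the pipeline and the
noise model, not a claim that the texture views help on real tissue — on real
MRI, texture statistics differ by tissue, which is the regime the mixture
generator emulates instead.

**Tabular mixtures.**  `generate_mixture_mvd` draws a latent class per sample
(given proportions), then per informative view a Gaussian around that class's
mean (default: 1-D views, means spaced `separation·sd` apart, separation 5);
optional pure-noise views are class-independent unit Gaussians.  Views are
z-scored per dimension after generation (`standardize=True`) so the views are
scale-commensurate, matching the image path's convention; separation measured
in within-class standard deviations is unchanged.  With the default geometry
the Bayes error per view is Φ(−2.5) ≈ 6·10⁻³ per adjacent-class boundary, and
the multi-view fit recovers the classes (ARI ≥ 0.95) in at least 18 of 20
seeds — this is the regime where the shared-structure assumption of the model
holds.

## Experiment harnesses (`mvfcm.pipeline`)

`segment_image` follows the image flow: optional median denoise → view
construction → clustering → fused partition → label map → metrics.  The FCM
baseline clusters the raw intensity view only, reproducing the classic
single-view flow; multi-view algorithms receive the constructed views.  C = 4
by default (background/CSF/GM/WM).  `grid_search` is exhaustive over named
parameter grids with deterministic tie-breaking.  `noise_experiment` draws a
fresh phantom geometry per seed, corrupts the same clean image at each noise
level, segments with each algorithm, and reports seed-averaged mean tissue JS
and DSC plus drop rates relative to the 0% baseline.  Problem sizes used
throughout (128×128 phantoms, 10 seeds, N = 200–300 mixtures) keep any single
experiment under a minute on one CPU while leaving the seed-averages stable to
the second decimal.

## Known limitations

- Euclidean distances make the model sensitive to view scaling and to high
  dimensionality; there is no kernelization or spatial regularization.
- The converged weight matrix is uninformative about view quality (see
  "Weight dynamics" above); diagnostic use of `W` should inspect the
  adaptation transient.
- The convergence test is an absolute objective difference (ε = 0.001 by
  default, matching the standard protocol); on large images the objective is
  of order 10⁴–10⁵ and the iteration cap (100) is usually what stops the run.
- The phantom's noise convention (σ as percent of full intensity range) is
  one of several in use; orderings across noise levels are robust to the
  convention, absolute scores are not.
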