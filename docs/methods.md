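# Methods

## Model

Each run's denoised ROI-by-time matrix `X ∈ R^{p×t}` is summarized by its
empirical covariance structure `K = XX′` (divided by `t` by default, see
*Numerical choices*). The generative model is a constrained probabilistic
PCA: latent activities `z ~ N(0, G)` project through a shared loading
matrix to observations `x | z ~ N(Wz, vI)`, so the model covariance is
`Σ = WGWᵀ + vI`. The loading matrix `W ∈ R^{p×k}` is non-negative,
column-orthonormal, and has at most one non-zero entry per row. Together
these constraints force a block structure: each column of `W` is a set of
ROIs disjoint from every other column — a brain network — and the diagonal
of the run-specific latent covariance `G` measures how much variance each
network carries in that run (its brain network activity, BNA). Rows of `W`
may be all-zero: an ROI can belong to no network.

Fitting minimizes the Gaussian discrepancy
`Σᵢ p log 2π + log det Σ⁽ⁱ⁾ + tr(Σ⁽ⁱ⁾⁻¹ K⁽ⁱ⁾)`, which is the negative
log-likelihood up to a positive factor; the reported likelihood is its
negation.

## Optimization

Block-coordinate descent with a monotone objective:

- **Latent update (exact).** At fixed orthonormal `W`, write `M = WᵀKW`
  with eigenvalues `λⱼ` and residual `r = tr K − tr M`. The optimal latent
  spectrum is `max(λⱼ − v, 0)` in the eigenbasis of `M`, and the optimal
  noise solves `v = (r + Σ_{λⱼ<v} λⱼ) / (p − k + #{λⱼ < v})`; the correct
  regime is found by scanning the sorted spectrum (at most `k+1`
  candidates). When no eigenvalue falls below `v` this reduces to
  `v = r/(p − k)`. The noise is floored at `v_min = 1e-8` to keep `Σ`
  invertible; a run whose residual variance is non-positive is flagged
  degenerate.
- **Loading update (projected gradient).** The Euclidean gradient of the
  summed discrepancy is `Σᵢ 2(Σᵢ⁻¹ − Σᵢ⁻¹KᵢΣᵢ⁻¹)WGᵢ`. A step is projected
  onto the constraint set by clipping negatives, keeping each row's largest
  entry, and normalizing columns — for a disjoint-support matrix the
  column normalization *is* the polar re-orthonormalization, so no
  iterative orthogonalization is needed. Steps are accepted only if they
  decrease the objective (backtracking halving from `1/‖grad‖`, up to 30
  halvings), which together with the exact latent update makes the
  objective trace non-increasing by construction.
- **Initialization and restarts.** Restart 0 starts from the entrywise
  absolute value of the top-`k` eigenvectors of the mean covariance,
  projected; later restarts apply a seeded random orthogonal rotation to
  that eigenbasis before projection. Default 10 restarts, `tol = 1e-6` on
  the relative objective change, `max_iter = 500`. A column that loses all
  its rows during projection is repaired by reassigning the weakest row of
  a multi-ROI column (seeded), so a restart is never wasted on an empty
  network.

## Model selection

`select_k` fits one model per candidate `k` on the training runs and
scores each by the summed discrepancy of the held-out runs, with `(G, v)`
re-estimated per held-out run at the fixed fitted `W`. The curve is
min–max normalized to [0, 1]. Because per-run latents are free on held-out
data, the curve typically flattens rather than turning upward past the
true dimension; the selection rule therefore treats all candidates within
`δ` of the minimum (default 1% of the curve range) as tied and picks, among
them, the `k` whose `W` assigns the most ROIs to networks, breaking
remaining ties toward the smallest `k`. This mirrors the intended use:
maximize anatomical coverage first, then parsimony.

## Preprocessing

Per ROI row: linear detrend → zero-phase band-pass (Butterworth order 2,
applied forward–backward with `sosfiltfilt`; default 0.0025–0.05 Hz) →
zero-phase spectral notch (DFT bins within 0.03 ± 0.002 Hz zeroed; exact
zero phase by construction) → optional confound regression (least-squares
projection onto the complement of the confound columns plus intercept) →
z-scoring to zero mean, unit variance. Constant rows after filtering raise
rather than produce NaNs. The filter order and the notch half-width are
configuration with the stated defaults; the stage order prevents confound
structure from re-entering filtered bands. The forward–backward filter
needs `t > 15` samples at order 2; shorter truncations are reported as
missing points by the learning-curve analysis.

`K` is normalized by `t` by default so that `(G, v)` are per-sample
variances independent of run length; `normalize=False` restores the raw
`XX′` convention (which simply scales `G` and `v` by `t` and leaves the
support of `W` unchanged — see the scale-consistency test).

## Network matching

A network is reduced to its set of ROI centroids, computed in world (mm)
coordinates through the NIfTI affine so that different atlases share a
physical frame. The distance between networks is the symmetrized
mean-of-closest-point Euclidean distance `d_MoC`; it is symmetric and
non-negative but not a metric (no triangle inequality), which is
documented rather than "fixed". Cross-atlas pairing is a global greedy
assignment on the `d_MoC` matrix (smallest remaining distance first, ties
broken lexicographically); an optimal Hungarian assignment is available
behind `method="optimal"` for sensitivity checks.

## Statistics and decoding

- **Group tests.** BNAs are non-negative and typically skewed, so the
  default comparison between condition groups is the unpaired two-sided
  rank-sum test; a `paired=True` option truncates groups to equal length
  and uses the signed-rank test for users who want the paired reading
  despite unequal group sizes. Shapiro–Wilk normality p-values are
  reported per network as a diagnostic only. All network × condition-pair
  raw p-values form one family for Benjamini–Yekutieli adjustment
  (valid under arbitrary dependence), and annotations follow the map
  `** : p ≤ 1e-2`, `*** : p ≤ 1e-3`, `**** : p ≤ 1e-4`, else `ns`,
  applied to adjusted p-values. Conditions with fewer than 3 runs are
  skipped with a warning.
- **Decoding.** Leave-one-subject-out: every run of the held-out subject
  is test data, which rules out subject leakage by construction. The base
  learner is an RBF-kernel SVM with `C = 1` and the `scale` gamma
  heuristic (inverse of feature count × feature variance), wrapped in a
  10-estimator bootstrap-aggregated ensemble; the alternative base learner
  is an all-threshold ordinal logistic model with L2 penalty strength 1,
  implemented in-package as a small scikit-learn-compatible estimator
  (L-BFGS on the all-threshold logistic loss; the fitted cut-points come
  out ordered automatically). A bootstrap draw containing a single class —
  possible on small training sets — falls back to a constant predictor
  rather than erroring. Validation accuracy is stratified 5-fold
  cross-validation on the training subjects (fold count reduced when a
  class has fewer runs than folds); the reported spread is across folds.
  Hyperparameters are fixed, not tuned in an inner loop. Balanced accuracy
  is the metric throughout; its chance level is 1/#classes.
- **Label schemes.** `Anesthesia` (awake = 0 vs any anesthetic = 1),
  `DeepModerate` (awake = 0, moderate = 1, deep = 2; ordinal), `All`
  (awake plus each distinct anesthetic condition). The mapping actually
  used is returned with the labels so any reading can be reproduced.
- **Importance and learning curve.** Permutation importance shuffles one
  BNA column at a time and reports the mean ± sd balanced-accuracy drop
  (negative values possible and reported as-is). The duration learning
  curve truncates the raw series, re-runs preprocessing from scratch,
  re-estimates per-run latents at the fixed fitted `W`, and re-runs the
  decoder for each duration.

## Synthetic data

The generator draws datasets from the model's own generative process. The
default configuration reproduces the target study design: 156 runs of 500
time points at TR = 2.4 s across six conditions (awake; deep ketamine;
moderate/deep propofol; moderate/deep sevoflurane) and five subjects, with
each condition confined to its three-subject subset so that
leave-one-subject-out splits behave as in the real design (the held-out
subject `J` sees no ketamine). Per-run BNA levels scatter around
condition-dependent means (default dispersion 0.2) and the noise variance
is uniform on (0.1, 0.3). The default effect vectors place the
awake-vs-anesthesia contrast mainly on network 1 and, weaker, network 4,
with moderate sedation between awake and deep levels — the qualitative
pattern the method is designed to surface; absolute levels are chosen for
testability, as no empirical per-condition effect sizes are available to
calibrate against.

What the generator does *not* emulate: hemodynamic autocorrelation (time
columns are i.i.d., matching the likelihood's exchangeability assumption;
an AR(1) switch exists for robustness experiments), motion artifacts,
scanner drift (beyond what the filter chain would remove), and
between-site variability. Passing recovery tests on this data therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions, not robustness to real-world violations of them.

## Benchmark problem sizes

The recovery and selection benchmarks run at p = 40 ROIs, k = 4 networks,
N = 30 runs of t = 300 time points, with condition effects at least five
dispersions apart and noise in (0.1, 0.3) — a scaled-down replica of the
study geometry that keeps the full benchmark suite in the minutes range on
one CPU while preserving the p ≫ k, N ≈ tens regime. Model selection uses
the grid k ∈ {2..8} with 2 restarts per fit; support/BNA recovery use 5
and 3 restarts respectively.

## Known limitations

- The objective is non-convex; restarts mitigate but do not eliminate
  dependence on initialization. Support recovery is reliable at the
  benchmark SNR but not guaranteed globally.
- The held-out discrepancy is nearly flat beyond the true `k` (free
  per-run latents absorb extra dimensions), so `k` selection leans on the
  coverage/parsimony tie-break rather than a sharp minimum.
- `d_MoC` pairing is greedy by default and can differ from the optimal
  assignment on adversarial geometries.
- Ordinal decoding assumes the `DeepModerate` classes are genuinely
  ordered on a single latent dimension; the SVM makes no such assumption.
- Atlas handling requires pre-aligned grids; no resampling is performed.
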