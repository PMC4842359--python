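# Methods

`ckainit` implements a supervised pretraining scheme for shallow feedforward
classifiers, aimed at the kind of tabular morphometric data used in
computer-aided dementia diagnosis: a few hundred per-structure volumes,
areas and thickness statistics per subject, and three diagnostic groups —
normal controls (NC), mild cognitive impairment (MCI) and Alzheimer's
disease (AD) — of which MCI is intermediate and heterogeneous.

## The model

### Alignment-maximizing projection

Given standardized features `x_i ∈ R^D` and labels `t_i ∈ {1..C}`, a matrix
`W ∈ R^{m1×D}` (`m1 ≤ D`) induces the Mahalanobis metric

    d_W(x_i, x_j)² = (x_i − x_j)ᵀ WᵀW (x_i − x_j) = ‖W x_i − W x_j‖²,

which is passed through a Gaussian kernel `k_ij = exp(−d_W²/2σ²)` to give a
sample-similarity matrix `K_W`. Class membership defines the binary label
kernel `B`, `b_ij = δ(t_i − t_j)`. The projection is chosen to maximize the
centered kernel alignment

    ρ(K_W, B) = ⟨HK_WH, HBH⟩_F / (‖HK_WH‖_F ‖HBH‖_F),
    H = I − N⁻¹11ᵀ,   ρ ∈ [0, 1] for PSD kernels,

so that the projected geometry agrees with the label geometry: same-class
pairs close, different-class pairs far. Centering is computed by
row/column/grand-mean subtraction (`H` is never materialized), O(N²).

The kernel family is fixed as Gaussian with `σ = 1`. This costs no
generality during optimization: rescaling `W` rescales every projected
distance, so a free bandwidth would be redundant with the scale of `W`.

### Gradient

The ascent uses the analytic gradient of ρ itself (not log ρ):

    ∂ρ/∂K = (B_c − (⟨K_c,B_c⟩/‖K_c‖²) K_c) / (‖K_c‖‖B_c‖)   (· _c = HXH)
    M_ij  = −(∂ρ/∂K)_ij · K_ij / (2σ²)
    ∂ρ/∂W = 4 W Xᵀ (diag(M1) − M) X,

the last line being the graph-Laplacian form of the pairwise sums. The
implementation is verified against central finite differences (relative
error < 1e-5 elementwise on batches of random instances) in the test suite
and re-measured by `scripts/acceptance.py`.

### Scale-normalized ascent

The optimizer is full-batch gradient ascent with backtracking: each
iteration proposes `W + step·‖W‖·g/‖g‖`, halving `step` (at most 20 times)
until ρ increases; the accepted-ρ trace is therefore strictly increasing,
and the relative step plus unit direction make the trajectory exactly
invariant to the overall scale of the data.

After every candidate step, `W` is rescaled so the **median pairwise
projected squared distance equals 1** — the median heuristic for the kernel
bandwidth, expressed as a constraint on `W` and held fixed throughout
(`OptimizerConfig.normalize_scale`, on by default). This constraint matters:
left free, the ascent inflates `‖W‖`, which is equivalent to shrinking the
bandwidth until every sample is far from every other; training alignment
then rises by pure memorization while held-out alignment degrades. The
test suite demonstrates this directly: on a synthetic cohort the
constrained ascent reaches strictly higher held-out alignment than the
unconstrained one. The
initialization is the top-`m1` PCA loadings of the standardized features
(deterministic; a seeded random init is available), normalized the same way.

Stopping: `max_iter` (default 150) or a candidate whose relative
improvement falls below `tol` (default 1e-6) — such a step is *not* taken,
so with `tol = ∞` the fit returns the normalized initialization unchanged.

Operating constraints inherited from the method: `2 ≤ m1 ≤ D` (the
projection must reduce dimension) and `N > m1`; meaningful generalization
of the learned metric additionally requires the training sample to exceed
the input dimension — with N_train < D the alignment overfits severely (we
observe exactly this when the constraint is violated).

### Relevance

The learned projection ranks input features by

    ϱ_d = (1/m1) Σ_u W_ud²,

the mean squared weight of feature `d` across projection rows; large values
mean the embedding depends on that feature. Both the raw vector and a
max-normalized version (most relevant feature = 1) are reported, plus
block-aggregated means for grouped displays; ranking ties break by
ascending feature index.

### Classifier

A one-hidden-layer network `D → m1 → C`: hidden layer
`h = φ(b¹ + W¹x)` with the tanh-form sigmoid `φ(z) = (tanh z + 1)/2`
(derivative `2φ(1−φ)`), softmax output with max-subtraction, and the mean
negative log-likelihood of the target class as loss (with a 1e-12
probability floor). A softmax layer's class scores always sum to one, so
the loss is the per-target `−log P(t_i | x_i)`, not a sum over classes.
Training is plain minibatch SGD (defaults: lr 0.05, batch 32, 300 epochs,
seeded shuffling) with optional early stopping: patience 20 on the loss of
a seeded stratified 10% holdout, restoring the best parameters. Backprop is
finite-difference-verified. Labels are 1-based at every public interface.

`init_network` places an `m1×D` projection in the first layer — the
alignment-learned `W*` verbatim, PCA loadings, autoencoder encoder weights,
or a seeded uniform(−r, r), `r = 1/√fan_in` — while biases and the output
layer are always random (seeded), whatever the strategy.

### Baselines

- **PCA**: top-`m1` right singular vectors of the centered data, unit norm,
  descending variance, each row's largest-magnitude entry made positive for
  cross-platform reproducibility.
- **Autoencoder**: sigmoid encoder, linear decoder, untied weights, MSE
  loss, seeded minibatch SGD (defaults: lr 0.05, batch 32, 200 epochs). The
  encoder weight matrix initializes the classifier's first layer.

### Evaluation

Accuracy `α = trace(confusion)/N`; per-class recall `τ^c`; one-vs-rest AUC
`β^c` by the trapezoidal rule over thresholds with tied scores grouped
(equal to the Mann–Whitney U statistic scaled by `n⁺n⁻` when scores are
tie-free); `β` is the class-size-weighted mean. `α` equals the
`N^c`-weighted mean of the `τ^c` — an identity of the trace form. Classes
absent from the truth get NaN recall/AUC and are excluded from `β` with a
warning. Note that a literal one-vs-rest count `Σ_c(tp^c+tn^c)/Σ_c N^c`
exceeds 1 for `C > 2`, so it cannot be what a percentage-scaled accuracy
reports; the trace form is used throughout.

Model selection: stratified, seeded 5-fold cross-validation over a grid of
hidden widths; the selected width maximizes the **mean-to-deviation ratio**
`mean/(std + 1e-8)` of fold accuracies (stability matters as much as level);
ties go to the smallest width.

## Synthetic cohorts

Real morphometric tables of this kind are not redistributable, so the
package ships a seeded generator that emulates their structure: five named
feature blocks — CV 70, SV 42, SA 72, TA 70, TS 70 (D = 324) — and default
per-class counts 655/825/513 (N = 1993). The class structure is
class-conditional Gaussian:

- only a designated informative subset carries signal (default: the first
  20 SV features — subcortical volumes are the block such analyses
  typically highlight);
- NC and AD means sit `effect_size` within-class standard deviations apart
  on those features (default 1.5, a moderate, realistically attainable
  morphometric separation);
- the MCI mean interpolates NC→AD (`mci_position`, default 0.5) and its
  standard deviation on the informative features is inflated
  (`mci_spread_multiplier`, default 2.0), encoding the intermediate,
  heterogeneous character of that group;
- all remaining features are mean-zero noise, independent standard normal
  by default or low-rank-plus-diagonal (`noise_cov="lowrank"`) to mimic
  global-size correlations.

What the generator does **not** emulate: real covariance structure between
morphometric measures, site/scanner effects, non-Gaussian tails,
label noise, and head-size normalization artifacts. Consequences: passing
tests demonstrate the correctness and internal behavior of the machinery,
not clinical performance; and because the synthetic class signal is a
rank-1 mean shift on a known block (plus one variance inflation), *any*
full-rank first layer preserves it, so a well-trained shallow net reaches
statistically indistinguishable test accuracy from random, PCA, autoencoder
or alignment initializations on these cohorts — the per-strategy accuracies
that `scripts/acceptance.py` recomputes sit within seed noise of one
another. On such data the measurable benefit of the alignment pretraining
is interpretability — the relevance vector concentrates on the truly
informative features — and a more discriminative low-dimensional embedding:
the acceptance script also reports a ridge linear probe that is more
accurate on the 14-dimensional projected space than on the raw
324-dimensional space, rather than a higher end-of-training accuracy.
Initialization-driven
accuracy gains of the kind reported on real MRI cohorts should be expected
only where training is less able to recover from an uninformative start
than early-stopped SGD on Gaussian data is.

Problem sizes used in the shipped experiments (chosen so that training-set
size comfortably exceeds D, the method's own operating requirement, while
keeping runs desk-scale): comparison experiments draw cohorts at 2/3-scale
class proportions (437/550/342, N = 1329) with a stratified 70/30 split;
relevance-recovery experiments use D = 50 with 10 informative features and
80 subjects per class.

A fixed 12-sample, 6-feature, 3-class table with hand-written constants
(`tiny_fixture`) supports exact, platform-independent regression tests.

## Numerical choices

- Degenerate kernels (constant, e.g. `W = 0` or single-class labels) raise
  a dedicated error rather than returning NaN.
- ρ is clipped to `[0, 1]` only against round-off (negative values above
  −1e-12; Cauchy–Schwarz bounds the top).
- Squared distances are symmetrized and clipped at 0 before the kernel.
- An all-zero projection yields an all-zero relevance vector with a warning
  (no division by zero).
- Feature standardization floors the per-feature sd at 1e-8; train-set
  statistics are always reused for validation/test data.
- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bitwise-identical projections, networks and cohorts.

## Known limitations

- The CKA objective is non-concave; the ascent finds a local maximum
  (deterministically, given the init and seed).
- Full-batch kernels are O(N²) memory and the gradient O(N²D) time,
  practical to N of a few thousand; no kernel approximation is provided.
- Single hidden layer as studied; deeper stacks, momentum/Adam and learned
  bandwidths are out of scope.
- The autoencoder baseline is deliberately minimal (no denoising/sparsity).
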