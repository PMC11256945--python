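# Methods

## The model

`deepida` addresses joint *association and discrimination* of two or
more data views — feature matrices `X_1 … X_D` (samples × features)
measured on the same `n` samples, each sample carrying one of `K` class
labels.  Typical inputs are preprocessed omics matrices (proteomics,
metabolomics, RNA-seq) with a clinical outcome.

Each view is passed through its own feed-forward network
`H_d = f_d(X_d)`, an MLP with activation applied on every layer
including the last.  On the top-layer representations we form, per
view,

* class means `mu_kd` and their unweighted mean `mu_d = (1/K) Σ_k mu_kd`,
* the between-class covariance
  `S_bd = (1/(n−1)) Σ_k n_k (mu_kd − mu_d)(mu_kd − mu_d)^T`,
* the total covariance `S_td` of all rows about `mu_d`,
* and for each pair of views the cross-covariance `S_dj` of the
  centered representations.

Note that `mu_d` is the mean of class means, *not* the grand sample
mean; for unbalanced classes the two differ, and the formulas above are
implemented with the mean-of-class-means convention throughout (the
grand-mean variant is a documented alternative a caller can obtain by
centering manually).

After whitening, `M_d = S_td^{−1/2} S_bd S_td^{−1/2}` and
`N_dj = S_td^{−1/2} S_dj S_tj^{−1/2}`, the objective over per-view
projection matrices `Γ_d` (orthonormal columns, `l ≤ min(K−1, o_d)`) is

```
max  c1 Σ_d tr(Γ_d^T M_d Γ_d)  +  c2 Σ_d Σ_{j≠d} ‖Γ_d^T N_dj Γ_j‖_F²,
c1 = ρ/D,   c2 = 2(1−ρ)/(D(D−1))
```

`ρ ∈ [0,1]` trades class separation against view association; `ρ = 0.5`
is the default.  For fixed networks the stationary conditions form a
coupled system of symmetric eigenproblems
`(c1 M_d + c2 Σ_{j≠d} N_dj Γ_j Γ_j^T N_dj^T) Γ_d = Γ_d Λ_d`, which the
solver iterates cyclically over views until the relative objective
change is below `1e−6` (at most 100 sweeps).  The networks themselves
are trained by maximizing `Σ_d Σ_{r≤l} λ_{d,r}`, the per-view sums of
the top `l` eigenvalues of those coupling matrices, with the `Γ`s held
fixed within each gradient step and re-solved each epoch.

## Gradients without an autodiff framework

The package is plain numpy/scipy.  The loss gradient with respect to
each `H_d` is assembled by reverse-mode matrix calculus:

* `d(Σ top-l eigenvalues of G)/dG = V V^T` with `V` the corresponding
  eigenvectors (exact wherever the l-th eigengap is positive; the sum,
  unlike individual eigenvectors, is stable under near-degeneracy);
* the map `S_t → (S_t + r I)^{−1/2}` is differentiated with the
  Daleckii–Krein formula in the eigenbasis of `S_t`, including the
  dependence of the relative ridge `r` on `diag(S_t)`; near-equal
  eigenvalue pairs fall back to the derivative limit `f′((s_i+s_j)/2)`;
* covariances and class means are linear maps of `H` with
  straightforward adjoints;
* layer gradients are standard backprop through the cached
  pre-activations.

A finite-difference test validates the whole chain end to end
(relative error below 1e−3 at the few weights probed; in practice it
agrees to ~1e−6).  Optimization is full-batch Adam (lr 1e−3 default)
with optional decoupled weight decay and a cosine step-size decay to
one tenth of the initial value; both are off by default.

## Numerical choices

* **Ridge.**  `S_td` is inverted after adding
  `1e−4 · mean(diag(S_td)) · I`; finite-sample top-layer scatter can be
  near-singular even when `o_d < n`.
* **Sign and ties.**  Eigenvector columns are sign-fixed by making the
  largest-magnitude entry positive; exact ties keep the
  eigendecomposition order.
* **`Γ` initialization.**  Seeded random matrices with orthonormalized
  columns, so runs are reproducible end to end.
* **Degenerate inputs.**  A single represented class, `o_d ≥ n`,
  mismatched row counts and NaNs are rejected with specific errors; a
  non-finite loss aborts training with a diagnostic rather than
  continuing.
* **Solver monotonicity.**  Each cyclic eigen-update maximizes its own
  view's coupled trace; the recorded objective trace is checked
  non-decreasing per sweep in the test suite (tolerance 1e−9).

## Classification

Prediction is nearest centroid (NCC) in a learned representation
space.  The default space is the pooled (concatenated) network outputs
of all views; single-view outputs and discriminant scores `H_d Γ_d`
are available as modes.  Ties go to the class earlier in sorted label
order.  Negative distances serve as decision values; multiclass AUROC
is macro one-vs-rest on softmaxed negative distances (there is no single canonical multiclass AUROC
construction, so this is a package choice).  Metrics (accuracy, balanced accuracy, AUROC,
precision/recall/F1 and their weighted variants) are thin wrappers over
scikit-learn.

## Bi-Bootstrap feature ranking

`M` stratified with-replacement bootstrap index sets (per-class counts
preserved) are paired 1:1, after a seeded shuffle, with `q = M` feature
subsets holding `floor(0.8 p_j)` distinct features per view.  Per pair:
fit a fresh model on the in-bag rows / subset columns, record a
baseline metric on the out-of-bag rows, then permute each subset
feature in the out-of-bag data one at a time and count a hit when the
metric drops *strictly* below the baseline (an unchanged metric is no
evidence).  The ranking statistic is `n_k / N_k`, hits over
evaluations; ranks sort by descending proportion with ties broken by
ascending feature index; `N_k = 0` features are reported with
proportion 0 and an `unevaluated` flag rather than dropped.  Pairs
whose out-of-bag set is empty or single-class are skipped and excluded
from both counts.  Because one trained model serves all of a pair's
permutations, a permuted-column forward pass is computed with an exact
rank-one update of the first-layer pre-activations (`O(n c_1)` instead
of `O(n p c_1)`), which is what makes the p = 2000 setting tractable.

Feature subsets are drawn *without* replacement: a with-replacement
draw would place duplicate column indices inside one subset, which is
incoherent for column selection.

The default ranking model is the joint fit scored by NCC on pooled
discriminant scores with **balanced accuracy** as the out-of-bag
metric: the benchmark settings all have unbalanced classes
(`n1 ≠ n2`), and balanced accuracy additionally takes fewer exactly
tied values than the raw classification rate, so strict-decrease
counting loses less information to ties.  Plain classification rate
and weighted F1 are config options.

## The synthetic-data generator

The nonlinear generator emulates a two-class, two-view spiral design.
`θ̃` is `n` evenly spaced points on `[0, 3π]`; `θ = θ̃ + 0.5·U(0,1)`
with independent per-sample jitter.  In view 1, columns 1–5 equal
`exp(0.15θ)·sin(1.5θ)`, columns 6–⌊0.1p₁⌋ equal
`exp(0.15θ)·cos(1.5θ)`, and the remaining 90% are standard normal; the
signal block is kept and the rest zeroed by an elementwise mask, then
`0.2·N(0,1)` noise is added everywhere.  View 2 is view 1 with
negatives clipped to zero, columns scaled to unit Euclidean norm, plus
per-entry `U(0,1)` noise — a view with no signal columns of its own.
Classes are assigned by position along `θ̃`: the first `n1` grid points
are class 1, the rest class 2, i.e. the two arms of the growing spiral.
Rows are then shuffled jointly.  Settings S1–S4 fix
`(n1, n2, p1=p2)` to (200, 150, 500), (3000, 2250, 500),
(200, 150, 2000) and (3000, 2250, 2000); 10% of view-1 features are
signals in every setting.

Two points in this construction are design choices of this package,
flagged here and configurable: the class assignment along the `θ`
grid (the spiral design itself does not dictate a class rule), and per-entry
rather than per-column `U(0,1)` noise in view 2.  A single `θ` vector
is shared by all signal columns, since the construction defines one
`θ` for the whole dataset.

What the generator does *not* emulate: heavy-tailed or count-valued
omics distributions, batch effects, missing values, and correlated
noise between features.  Tests passing on this generator therefore
demonstrate the machinery (optimization, ranking, selection) rather
than robustness to real-data pathologies.

The linear toy (`generate_linear_toy`) is a fast fixture — two Gaussian
class clouds sharing a latent factor across two views — used for smoke
tests and CLI examples, not for benchmarks.

## Benchmark harness and problem sizes

`cli_io.classification_experiment` draws independent
(train, validation, test) triples per Monte-Carlo replicate, trains
each candidate in a small grid — widths (256, 64) / (512, 128), top
layers 10/20, 50 or 100 epochs, all three-layer — and selects by pooled
NCC accuracy on the validation set, reporting test accuracy for the
view-1 and pooled modes plus a linear-kernel SVM on the stacked raw
views.  Views are z-scored with training statistics (the package
default).  `cli_io.ranking_experiment` runs the Bi-Bootstrap on fresh
datasets and scores the top-10% selection against the known signal
mask.  For ranking, the internal trainer runs on raw (unstandardized)
columns — the generator's features share a meaningful common scale, and
z-scoring would inflate the pure-noise columns — with weight decay 1e−2
and cosine step decay over 100 epochs.

The shipped acceptance script uses 5 ranking replicates with M = 20
bootstrap pairs for the small setting, 3 replicates with M = 10 and
samples stratified-subsampled to one third for the large-n setting,
3 replicates with M = 10 for the p = 2000 setting, and 12 Monte-Carlo
replicates for the small-setting classification comparison (enough to
hold the Monte-Carlo error of the reported means near half a point);
these sizes are the package's scaled-down defaults and are stated in
the script's output.

## Known limitations

* With `M` bootstrap pairs each feature is evaluated roughly `0.8 M`
  times, so occurrence proportions have Binomial resolution `~1/(0.8M)`.
  Highly redundant signal blocks (45 near-copies of one curve in S1,
  195 in S3) give each individual column a small marginal effect, and
  at M = 10–20 the weakest columns' proportions overlap the luckiest
  noise columns'.  Selection is near-perfect for the strong columns
  (the five sine columns rank at proportion 1.0 essentially always)
  and degrades gracefully for the redundant tail; larger M sharpens the
  separation.
* The pooled nearest-centroid mode weights all representation
  coordinates equally; a view whose representation carries no class
  signal dilutes the pooled distances.  How strongly it dilutes depends
  on the relative output scales of the per-view networks, which the
  objective does not pin down.
* Training is full-batch; mini-batch covariance corrections are out of
  scope, so memory grows linearly with `n · max(p_d)`.
* The loss treats classes by their counts (`n_k` weights in `S_bd`);
  severely unbalanced designs are not reweighted.
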