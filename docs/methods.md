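# Methods

## Model family and estimation

The three estimators share the linear score model `S(X) = XZ + ep^T` with
argmax decoding (ties to the lowest column index; the column order is the
sorted order of the original labels). Estimation:

* **LSR**: the ridge normal equations `(X^T X + λI)Z = X^T Y`, solved as a
  symmetric positive-definite system (Cholesky via `scipy.linalg.solve(...,
  assume_a="pos")`). λ > 0 is required, which guarantees invertibility; the
  offset is fixed at `p = 0`.
* **DLSR**: alternating exact minimization of
  `||XZ + ep^T - (Y + B∘W)||² + λ||Z||²` over the blocks `(Z, p)` and
  `W ≥ 0`. The slack starts at `W = 0`, so iteration 1 is plain ridge
  regression on `Y` — a deterministic, convexity-friendly start. The
  `(Z, p)` block is solved by removing column means from `X` and `L`
  (implicitly applying the centering projector `H = I − ee^T/N` without
  materializing it; `X_c^T L_c = X^T H L` exactly, in exact arithmetic) and
  back-substituting `p = mean(L) − Z^T mean(X)`. The `W` block separates
  per entry because `B_ij² = 1`, giving the clamp `W = max(B∘G, 0)`.
* **TDLSR**: same alternation with the `(Z, p)` system augmented to
  `(X_c^T X_c + (λ+η)I)Z = X_c^T L_c + ηZ_s`. Only `Z` is penalized toward
  the source, so `p` is always relearned on the target — deliberate, since
  a domain shift typically moves the offset even when the discriminant
  direction transfers. The `η = 0` branch takes the identical code path as
  DLSR, so the reduction holds bitwise, not just to tolerance.

**Stopping rule** (none is inherited from the formulation): stop when the
relative objective change `|J_t − J_{t−1}| / max(1, J_{t−1})` falls below
`tol` (default 1e-6), or after `max_iter` (default 50) iterations. On
well-separated data the dragging objective keeps creeping downward as
targets drag further outward, so hitting `max_iter` unconverged is normal
and harmless — the decision boundary stabilizes long before the objective
does.

**Source knowledge**: `Z_s` is extracted by fitting DLSR on the source
domain (configurable to LSR). Transferring the same model family that is
fit on the target is the natural default; provenance (estimator, λ, sample
count, convergence) is recorded on the `SourceKnowledge` object and in the
serialized model JSON.

## Synthetic domain pairs

`make_domain_pair` draws class-conditional Gaussians with unit covariance
and class means `√2·e_c`, so every pair of class means is exactly 2 apart
(two within-class standard deviations — separable but overlapping,
matching the regime where the reported accuracies live). Target
distributions are either identical, mean-shifted by `shift_magnitude`
(default 1.0, i.e. half the class separation) in an independent random
unit direction per class, or have their first two class means swapped. An
independent direction per class was chosen over a single global
translation because a global shift is fully absorbed by relearning `p`,
which would make transfer trivially perfect; per-class shifts perturb both
offset and orientation, as real cross-condition EEG shifts do. The target
is split per class with `floor(test_fraction · n)` test points, so the
75-per-class source / 25-per-class target with 20% testing reproduces the
75+75 / 25+25 / 5+5 protocol arithmetic exactly.

**Source noise**: "x% white Gaussian noise" is read as additive
independent noise with per-feature σ equal to `x · σ_j` of the source
feature, applied to all source samples — the signal-relative convention.
The alternative reading (corrupt a random x% of samples) is available via
`mode="sample_fraction"`. Noise is applied to features, not raw signals,
because the estimators consume feature vectors.

What the generator does *not* emulate: temporal structure, non-Gaussian
feature distributions, class imbalance, and the specific geometry of EEG
band-power features. Passing tests therefore certify the optimization and
protocol machinery and the qualitative transfer behavior on well-specified
Gaussian data — not clinical performance on real EEG.

A consequence worth knowing: on symmetric Gaussian clouds, adding
feature-proportional noise to the source acts mostly as coefficient
attenuation and barely moves the decision boundary, so at the 15% level the
pooled estimators' degradation is within Monte-Carlo error of zero at
desk-scale sample sizes. The qualitative noise-direction check in the
experiment example/test therefore uses 30% noise in the shifted-scarce
regime, where all estimators measurably degrade; the 15% level is kept for
the transfer-comparison study, where the transfer model's degradation
(through `Z_s`) is visible and the target-only model is untouched by
construction.

## Evaluation protocol

`run_experiment` mirrors the source/target evaluation design: per seed, a
domain pair is generated (or assembled from Bonn-style files), optionally
source-corrupted, and each estimator is tuned by stratified k-fold CV
(default 5) **on the target training split only**, then scored on the
target test split. Ties in CV accuracy break toward smaller λ, then
smaller η. Non-transfer estimators (LSR, DLSR, SVM) train on the pooled
source + target-train data by default (`pool_source: true`) — the reading
under which a corrupted source degrades them, consistent with the original
noisy-source comparisons; `pool_source: false` switches to target-only
training, the right comparison for "does transfer beat ignoring the
source?". Default grids: λ, η ∈ {10⁻⁴, 10⁻³, …, 10²} (7 values each; 49
TDLSR combinations); the RBF-SVM baseline (scikit-learn `SVC`) uses
C, γ ∈ {2⁻⁵, …, 2⁵}. Results are a pure function of (config, seeds); 20
seeded repeats with the mean reported is the default repetition scheme.

## EEG ingestion

Bonn-style segments are ASCII, one sample per line (comma/whitespace
tolerated), nominally 4097 samples at 173.61 Hz; other lengths set a
warning flag rather than failing. The default featurization is log mean
periodogram power in the five classical bands (0.5–4, 4–8, 8–13, 13–30,
30–60 Hz; all below the 86.8 Hz Nyquist), with a binned-mean
`raw_downsample` alternative; features are z-scored using statistics of
the source + target-train segments only, so the test split never
influences scaling. When source and target recipes differ by set letter
(e.g. source "BE", target "BC"), classes correspond positionally by
recipe order — the i-th letter of each recipe is class i; the cross-domain
correspondence is otherwise undefined.

## Numerical choices and edge cases

* All SPD systems are solved, never inverted; λ > 0 enforced at fit time,
  η = 0 permitted (the reduction case).
* `FitTrace.objective_values` is recorded after each complete (Z, p, W)
  iteration; monotonicity is guaranteed analytically and asserted in tests
  with 1e-9 relative slack for floating-point headroom.
* Degenerate inputs: all-zero features yield `Z = 0`, `p = column means`;
  constant targets are absorbed entirely by `p`; empty prediction input
  returns an empty label sequence; fewer than two distinct labels is an
  error, as is a source/target class-set or shape mismatch.
* The scarce-target studies use fixed λ = 0.01 and η = 1.0 rather than CV:
  with 2 training points per class, cross-validation estimates are close
  to noise, and a small fixed ridge plus an equal-weight transfer pull is
  the defensible default.
* Study sizes (20 seeds, 75 source / 10 target points per class, d = 8)
  keep every study deterministic and small while leaving the reported
  orderings well outside Monte-Carlo error.

## Known limitations

* No kernelization and no multi-source transfer.
* The SVM baseline is a convenience comparator, not a tuned reference.
* Gaussian synthetic data understate the harm of source noise (see above)
  and cannot validate feature-extraction choices for real EEG.
* `class_swap` pairs model label-correspondence failure; no estimator here
  is expected to survive it — it exists to probe negative transfer.
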