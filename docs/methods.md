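# Methods

## The model

`ecnn` trains a feed-forward binary classifier on a patient × event-code
count matrix `X ∈ ℝ^{n×p}` (counts min-max scaled to [0, 1] per feature)
with a default architecture `[p, 50, 30, 1]`: two hidden layers of 50 and
30 perceptrons and a single sigmoid output unit. The distinguishing
elements are:

1. **A bounded, entropy-regularized first layer.** First-layer weights are
   constrained to [0, 1] by projection (elementwise clamp) after every
   optimizer step, and the training cost is

   C = mean[−(y·log ŷ + (1−y)·log(1−ŷ))] + λ·(−Σ_{jk} w_{jk} log w_{jk}),

   with the penalty running over the first weight matrix only and natural
   logs throughout. On [0, 1] the penalty term −w log w is zero exactly at
   w ∈ {0, 1} and maximal at w = 1/e, so minimizing it drives each weight
   to one of the extremes: the first layer becomes a near-binary
   connect/disconnect gate on the input features.

2. **Snapshot ensembles under cyclic cosine annealing.** One network is
   trained for T epochs of plain mini-batch SGD whose learning rate follows
   α(t) = (α₀/2)(cos(π·mod(t−1, ⌈T/M⌉)/⌈T/M⌉) + 1): within each of the M
   cycles the rate decays from α₀ towards zero, then snaps back. The
   parameters at the end of each cycle form an M-member ensemble; the
   prediction is the unweighted mean of the member probabilities.

3. **Feature Sparsity Importance.** For feature k with gate column W¹_k
   (its weights into the J units of the first hidden layer),

   R_k = ( mean|W¹_k| − σ²(|W¹_k|) ) / max_k mean|W¹_k|,

   with the sample (J−1) variance. Fully connected features (high mean,
   low variance) score near 1, element-wise-sparse ("partially connected")
   features are penalized through the variance term, disconnected features
   score near 0. Each snapshot is scored with its own max-normalization and
   the M vectors are averaged. R_k can be negative when the variance
   exceeds the mean; negative values are kept for ranking and floored at
   zero only inside the cumulative-mass selection policy.

   Three thresholding policies operate on the aggregated vector: top-k
   (default k = 10), outliers above μ + 3σ of a moment-matched normal fit
   of all values, and the smallest descending prefix holding 95% of the
   total importance mass.

## Dynamics: why the defaults look the way they do

Gradient descent on the penalty has a watershed at w = 1/e ≈ 0.368:
below it the entropy force pushes a weight towards 0, above it towards 1.
Two consequences shaped the defaults.

* **Initialization sits just below the watershed.** First-layer weights
  start uniform on [0.2, 0.35]. If weights started above 1/e, the penalty
  itself would promote uninformative features to full connection and the
  ranking would be meaningless (verified empirically: an upper bound of
  0.4 destroys recovery outright). Starting below it makes disconnection
  the default fate; only features with persistent data gradient are pulled
  across the watershed, after which both forces push them towards 1.
  Placing the interval *near* the watershed, where the drift −(log w + 1)
  is weakest, lengthens the window in which data gradients can act. This
  reproduces the expected signature on trained models: importance mass
  concentrated near zero with a handful of high-importance outliers.

* **w = 0 is absorbing, so the first cycle is a capture race.** The
  penalty's derivative −(log w + 1) diverges as w → 0 (capped at −log ε by
  the floor), so a weight that reaches 0 cannot re-enter training. Every
  informative feature must accumulate enough data gradient before the
  entropy drift extinguishes it; a feature missed in the first cycle is
  never reconsidered. λ sets the two-sided trade: smaller λ lets
  weakly-prevalent informative features win the race but leaves noise
  stragglers alive on signal-free data, inflating the importance
  distribution's tail (at λ = 0.003 the 3σ policy picks several pure-noise
  features on null cohorts). The default λ = 0.01 sits at the clean point —
  on null data every gate weight dies and the importance vector collapses
  to zero — with batch size 64 giving enough (noisier) steps per epoch for
  informative features at the generator's prevalence to be captured.

* **Restarts can kill rectified units irreversibly.** With a pure
  rectifier, a learning-rate spike can push a whole hidden layer into the
  dead regime, freezing training at chance. The default hidden activation
  is a leaky rectifier (slope 0.01), which preserves the gating reading of
  the first layer while keeping every unit recoverable; plain `relu` and
  `linear` remain selectable. For the same reason α₀ defaults to 0.05 —
  at 0.1, restart spikes destabilized training on these cohorts.

* **Every cycle must converge before its snapshot is taken.** A
  half-trained snapshot has an unpolarized gate whose importance vector is
  noise; averaged in, it can bury the signal of the converged snapshots.
  With M = 5 the default budget is T = 1000 epochs (cycles of 200).

## Tunable parameters

| field | default | meaning |
|---|---|---|
| `hidden_sizes` | (50, 30) | hidden perceptron counts (method-fixed) |
| `reg_lambda` | 0.01 | entropy penalty coefficient λ |
| `alpha0` | 0.05 | initial learning rate α₀ |
| `epochs` | 1000 | total epochs T |
| `n_snapshots` | 5 | cosine cycles / ensemble members M |
| `batch_size` | 64 | mini-batch size |
| `hidden_activation` | leaky_relu | hidden-layer nonlinearity |
| `init_range` | (0.2, 0.35) | first-layer uniform init interval |
| `cv_k`, `cv_repeats` | 5, 2 | repeated k-fold protocol (method-fixed) |
| `top_k` | 10 | top-k selection size (method-fixed) |
| `n_sigma` | 3.0 | outlier-policy threshold |
| `cumulative_quantile` | 0.95 | cumulative-mass policy quantile |
| `stepwise_tol` | 0.002 | backward-stepwise accuracy tolerance |

Serialized configs flag each field as `method_fixed` true/false so
implementation defaults are never mistaken for method constants.

## The synthetic cohort generator

Real cohorts of this kind are not publicly distributable, so the package
ships a generator that emulates their structure: cell occupancy is
Bernoulli(1 − sparsity), occupied cells draw a count from a geometric
distribution with mean `count_dispersion`, and labels follow a logistic
model on the standardized planted columns, with an
`interaction_fraction` share of the planted features contributing only
through pairwise products (a purely multivariate, non-linear signal).
`signal_strength` scales the linear predictor; at 0 the labels are fair
coins independent of every feature. Defaults: 2 000 patients × 500 codes,
85% empty cells, counts averaging 1.5, 10 planted features (one
interaction-only pair), signal strength 5 — a regime in which the planted
signal is comfortably learnable by a logistic regression given the true
columns, so failures to recover it are attributable to the method.

What the generator does **not** emulate: visit timestamps and the
within-window temporal structure of events, code-hierarchy correlations
(real event codes co-occur in clinically structured blocks), covariate
shift between practices, and vocabulary sizes in the tens of thousands.
Passing the recovery benchmarks here shows the machinery works at desk
scale under independent features; it does not certify behaviour under the
correlated, much wider feature spaces of real records.

## Evaluation protocol

Cross-validation uses k folds with cyclic role rotation (one fold test,
the next validation, the rest training), repeated with fresh partitions —
k × repeats evaluations in total. Min-max statistics are always fitted on
the training role and applied frozen to the other roles; feature ranking
trains on the training+validation roles of the plan's first evaluation
only, so the test role never influences selection. Metrics with a zero
denominator propagate as NaN and are excluded (and counted) in
aggregation. Baselines: a random-forest permutation-importance ranking
(scikit-learn), uniformly random subsets of equal size, and a paired
two-sided t-test over the shared folds for method comparisons; the t-test
refuses zero-variance differences rather than reporting a meaningless
statistic.

Backward-stepwise elimination retrains without each candidate feature and
drops the least-costly one until every removal costs more than the
tolerance. Candidate evaluations within a step share one training seed and
are averaged over three restarts: subset comparisons are then paired, not
confounded by training noise. Even so, on small cohorts the procedure is
noisy; its contract is majority behaviour over seeds, not determinism of a
single run.

## Numerical choices

* Logs use a floor of ε = 1e-12; predictions are clipped to [ε, 1−ε].
* The entropy penalty is implemented exactly as −w·log(max(w, ε)) with
  gradient −(log w + 1) for w > ε and −log ε below; analytic gradients
  match central finite differences to 1e-4 on small networks.
* Cross-entropy is averaged (not summed) over the batch, so λ's meaning
  is batch-size independent.
* Training arithmetic is single precision (float32) — ample for every
  statistic computed here and twice as fast on one CPU; the gradient
  checker runs in double precision.
* Per-epoch training loss in the history is the running mean of batch
  cross-entropies plus the end-of-epoch penalty (no extra full forward
  pass); validation loss is computed exactly once per epoch.
* Deeper layers use He-style normal initialization; epoch indexing is
  1-based; snapshot capture occurs at epochs where mod(t−1, ⌈T/M⌉) equals
  ⌈T/M⌉−1, plus the final epoch if T is not divisible by M.
* Ties in selection are broken by ascending feature name; fold sizes
  differ by at most one.

## Known limitations

* The absorbing-zero dynamics mean features missed in the first cycle are
  never reconsidered; snapshot diversity exists only among weights still
  alive. Interaction-only feature pairs (signal in the product, weak
  margins) are usually *not* recovered at default prevalence — the
  recovery benchmark asks for 8 of 10 planted features for exactly this
  reason.
* The importance metric penalizes element-wise sparsity by subtracting a
  variance, so a feature serving a few hidden units scores barely above
  the noise floor even when it is genuinely predictive; rankings are
  reliable only when every snapshot has converged.
* The metric's claimed [0, 1] normalization does not hold algebraically
  (R_k < 0 whenever σ² > mean); values are reported as computed.
* Training one network per CV evaluation is the dominant cost; the
  package is deliberately CPU-only and single-threaded-friendly.
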