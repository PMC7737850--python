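# ecnn — entropy-regularized snapshot ensembles for sparse coded-event data

`ecnn` is a feature-selection and risk-prediction toolkit for the kind of
data primary-care records produce: a patient × event-code count matrix
with tens of thousands of one-hot code features, extreme sparsity (each
patient touches a tiny slice of the vocabulary), and a binary outcome such
as "hospitalized after diagnosis". Classical pipelines struggle here —
embedding-based reductions (PCA and relatives) destroy the interpretability
of individual codes, and per-feature statistics miss multivariate signal.

The method trains a feed-forward classifier whose first layer is a
learnable gate: its weights are bounded to [0, 1] by projection and
penalized by an entropy term λ·Σ −w log w, which is zero only at w ∈ {0, 1}.
Training therefore drives each input connection to "connected" or
"disconnected", with prediction loss deciding which. One training run
yields an M-member ensemble by saving parameters at the end of each cycle
of a cyclic cosine learning-rate schedule,

    α(t) = (α₀/2) · (cos(π · mod(t−1, ⌈T/M⌉) / ⌈T/M⌉) + 1),

and features are ranked by Feature Sparsity Importance,

    R_k = ( mean|W¹_k| − σ²(|W¹_k|) ) / max_k mean|W¹_k|,

averaged over snapshots — high for fully connected features, penalized for
element-wise sparsity, near zero for disconnected ones. Subsets come from
top-k, 3σ-outlier, or cumulative-mass thresholding, and are validated under
a repeated k-fold protocol with train/validation/test role rotation,
against random-forest and random-subset baselines, with optional
backward-stepwise refinement. Since cohorts of this kind are not publicly
distributable, the package ships a synthetic-cohort generator with planted
signal features, making recovery claims testable end to end.

## Worked example

```python
import numpy as np
import ecnn

cohort = ecnn.generate_cohort(ecnn.SimConfig(seed=1))   # 2000 x 500, 10 planted
X, _ = ecnn.normalize(cohort)
ensemble = ecnn.train_snapshots(X, cohort.labels, ecnn.TrainConfig(seed=101))

polarization = np.mean([np.mean((W <= 0.1) | (W >= 0.9))
                        for W in ensemble.first_layers])
report = ecnn.importance_report(ensemble, cohort.feature_names)
top10 = ecnn.select_topk(report.aggregated, report.feature_names, 10)
planted = {cohort.feature_names[i] for i in cohort.planted_features}
print(f"polarization {polarization:.3f}")
print(f"importance fit mu={report.distribution_fit[0]:.4f} "
      f"sigma={report.distribution_fit[1]:.4f}")
print(f"recovered {sum(n in planted for n in top10.names)}/10 planted features")
```

prints (a few minutes on one CPU):

```
polarization 1.000
importance fit mu=0.0006 sigma=0.0063
recovered 8/10 planted features
```

Read: effectively all gate weights resolved to the extremes; the importance
distribution concentrates near zero (the 490 noise features) with a few
high outliers; the top-10 ranking finds 8 of the 10 planted features — the
missing two form the interaction-only pair whose signal lives purely in a
product term. The scripts in `examples/` walk through cohort generation,
training and ranking, cross-validated subset comparison, and
backward-stepwise refinement.

A thin CLI mirrors the library for shell use:

```sh
ecnn simulate --seed 1 --out cohort/
ecnn run cohort/ --out results/     # CV + ranking + selection + re-evaluation
```

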