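"""Train one entropy-regularized snapshot ensemble and rank the features.

Training drives the [0, 1]-bounded first-layer weights towards a binary
connect/disconnect gate; the Feature Sparsity Importance metric then ranks
features from the gate columns, averaged over the snapshots captured at
the end of each cosine learning-rate cycle.  Takes a few minutes on one CPU.
"""

import numpy as np

import ecnn

cohort = ecnn.generate_cohort(ecnn.SimConfig(seed=1))
X, _ = ecnn.normalize(cohort)

config = ecnn.TrainConfig(seed=101)
ensemble = ecnn.train_snapshots(X, cohort.labels, config)

polarization = np.mean([np.mean((W <= 0.1) | (W >= 0.9))
                        for W in ensemble.first_layers])
print(f"snapshots captured: {ensemble.n_members}")
print(f"first-layer weights within 0.1 of {{0,1}}: {polarization:.1%}")

report = ecnn.importance_report(ensemble, cohort.feature_names)
mu, sigma = report.distribution_fit
print(f"importance distribution: mu={mu:.4f}, sigma={sigma:.4f}")

top10 = ecnn.select_topk(report.aggregated, report.feature_names, 10)
planted = {cohort.feature_names[i] for i in cohort.planted_features}
hits = sum(name in planted for name in top10.names)
print("top-10 features (planted marked *):")
for name, value in top10.selected:
    mark = "*" if name in planted else " "
    print(f"  {mark} {name}  R={value:.3f}")
print(f"recovered {hits} of {len(planted)} planted features")

outliers = ecnn.select_outliers(report.aggregated, report.feature_names, 3.0)
print(f"3-sigma outlier policy selects {len(outliers.selected)} features")

# A polarization above ~90% means the entropy penalty resolved almost every
# gate weight; a low mu with a handful of high-R outliers is the signature
# of a few informative codes standing out of an uninformative background.
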