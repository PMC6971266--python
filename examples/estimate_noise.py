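"""Estimate a confounder noise model from a paired side study.

Builds a small scan-rescan style side study (30 subjects measured under two
acquisition conditions), estimates the per-feature noise model, and compares
it with the generating parameters.
"""

import numpy as np

from dafit import FeatureTable, SideStudy, estimate_noise_paired

rng = np.random.default_rng(7)
n_subjects, n_features = 30, 5
names = [f"feat{j}" for j in range(n_features)]

true_mu = np.array([0.0, 0.5, -1.0, 0.0, 2.0])     # systematic shift per feature
true_sd = np.array([0.1, 0.5, 0.3, 1.0, 0.2])      # measurement noise per feature

base = rng.normal(size=(n_subjects, n_features))
rescan = base + true_mu + rng.normal(size=base.shape) * true_sd

side = SideStudy(
    mode="paired",
    a=FeatureTable(values=base, feature_names=names),
    b=FeatureTable(values=rescan, feature_names=names),
)
model = estimate_noise_paired(side)

print(f"{'feature':>8} {'mu_hat':>8} {'sd_hat':>8} {'true_mu':>8} {'true_sd':>8}")
for j, name in enumerate(names):
    print(f"{name:>8} {model.mu[j]:8.3f} {np.sqrt(model.sigma2[j]):8.3f} "
          f"{true_mu[j]:8.3f} {true_sd[j]:8.3f}")
print()
print("mu_hat / sd_hat: per-feature mean shift and noise level the confounder")
print("induces, estimated from 30 paired measurements; with this few subjects")
print("the estimates track the generating values to within sampling error.")
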