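"""Compare side-study strategies on a small confounded benchmark.

Generates a synthetic study (300 features, 20 informative, shifted test set),
then benchmarks ignoring the side study ("simple"), deleting unstable
features ("filtering") and noise augmentation ("proposed") with a random
forest under nested cross-validation.  Takes about a minute.
"""

from dafit import (
    BenchmarkConfig,
    ClassifierSpec,
    StrategySpec,
    run_experiment,
)

cfg = BenchmarkConfig(
    n_features=300, n_informative=20,
    n_train_per_class=60, n_test_per_class=100, seed=1,
)
rf = ClassifierSpec("random_forest", params={"n_estimators": 60},
                    tuning_grid={"min_samples_leaf": [1, 5]})
strategies = [
    StrategySpec("simple"),
    StrategySpec("filtering", filter_method="ccc"),
    StrategySpec("proposed"),
]

result = run_experiment(cfg, strategies, [rf], n_repeats=3, base_seed=2,
                        n_side_subjects=30, use_known_noise=True)
summary = result.summary(n_boot=500, seed=0)
cols = ["strategy", "mean_cv_auc", "mean_min_test_auc", "mean_aee"]
print(summary[cols].round(3).to_string(index=False))
print()
print("mean_cv_auc is what a practitioner would report from cross-validation;")
print("mean_min_test_auc is what the model achieves on the confounder-shifted")
print("test group; mean_aee is the gap between the two.  'simple' overstates")
print("its performance, 'filtering' pays with model strength, and the")
print("augmentation strategy keeps the estimate honest without discarding")
print("informative features.")
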