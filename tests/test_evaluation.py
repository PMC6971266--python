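import logging

import numpy as np
import pytest
from scipy import stats

from dafit import (
    BenchmarkConfig,
    ClassifierSpec,
    FeatureTable,
    StrategySpec,
    StudyBundle,
    auc,
    bootstrap_ci,
    generate_bundle,
    importance_overlap,
    run_experiment,
    run_strategy,
)
from dafit.evaluation import AllFeaturesRemovedError, StrategyResult


def _fast_rf():
    return ClassifierSpec(
        "random_forest", params={"n_estimators": 30}, tuning_grid={"min_samples_leaf": [1]}
    )


@pytest.fixture(scope="module")
def tiny_bundle():
    cfg = BenchmarkConfig(
        n_features=120, n_informative=10, n_train_per_class=30,
        n_test_per_class=50, seed=42,
    )
    return generate_bundle(cfg, n_side_subjects=25)


class TestAUC:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),   # perfect ranking
            ([0.6, 0.4, 0.7, 0.2], [1, 0, 0, 1], 0.25),  # 1 of 4 pos/neg pairs won
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),   # all ties count half
        ],
    )
    def test_hand_computed_values(self, scores, labels, expected):
        assert auc(np.array(scores), np.array(labels)) == pytest.approx(expected)

    def test_matches_mann_whitney(self, rng):
        """AUC equals the Mann-Whitney U statistic scaled by n_pos * n_neg."""
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        expected = u / (np.sum(labels == 1) * np.sum(labels == 0))
        assert auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestBootstrapCI:
    def test_constant_vector(self):
        lo, hi = bootstrap_ci(np.full(10, 3.25), seed=0)
        assert lo == hi == 3.25

    def test_interval_brackets_the_mean(self, rng):
        for seed in range(5):
            vals = np.random.default_rng(seed).normal(size=30)
            lo, hi = bootstrap_ci(vals, seed=seed)
            assert lo <= vals.mean() <= hi

    def test_coverage_of_true_mean(self):
        """~95% of intervals over repeated N(0,1) samples cover 0."""
        rng = np.random.default_rng(17)
        covered = 0
        n_rep = 300
        for i in range(n_rep):
            vals = rng.normal(size=100)
            lo, hi = bootstrap_ci(vals, n_boot=400, seed=i)
            covered += lo <= 0.0 <= hi
        assert 0.91 <= covered / n_rep <= 0.985

    def test_too_short_vector(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0]))


class TestImportanceOverlap:
    def _result(self, ranking, n_features=50):
        top = [(int(i), f"f{i}", float(n_features - r)) for r, i in enumerate(ranking)]
        return StrategyResult(
            strategy="simple", classifier="random_forest",
            cv_auc=0.5, test_aucs=[0.5], min_test_auc=0.5, aee=0.0,
            n_features_used=n_features, top_importances=top,
        )

    def _truth(self, informative, n_features=50):
        from dafit import BenchmarkTruth, NoiseModel

        return BenchmarkTruth(
            informative=np.asarray(informative),
            true_shift=NoiseModel(mu=np.zeros(n_features),
                                  sigma2=np.zeros(n_features), source_mode="known"),
            base_mean=np.zeros(n_features),
            base_sd=np.ones(n_features),
        )

    def test_all_informative_first(self):
        truth = self._truth(list(range(20)))
        res = self._result(list(range(50)))
        out = importance_overlap(res, truth, top_k=20)
        assert out == {"n_meaningful_in_top_k": 20, "prefix_meaningful": 20}

    def test_no_informative_in_top(self):
        truth = self._truth(list(range(30, 50)))
        res = self._result(list(range(50)))
        out = importance_overlap(res, truth, top_k=20)
        assert out == {"n_meaningful_in_top_k": 0, "prefix_meaningful": 0}

    def test_prefix_stops_at_first_noise_feature(self):
        truth = self._truth([0, 1, 5])
        res = self._result([0, 1, 2, 5] + list(range(6, 50)) + [3, 4])
        out = importance_overlap(res, truth, top_k=4)
        assert out["n_meaningful_in_top_k"] == 3
        assert out["prefix_meaningful"] == 2

    def test_top_k_bounded(self):
        truth = self._truth([0])
        res = self._result(list(range(50)))
        with pytest.raises(ValueError):
            importance_overlap(res, truth, top_k=51)


class TestRunStrategy:
    def test_result_contract_and_determinism(self, tiny_bundle):
        bundle, truth = tiny_bundle
        spec = StrategySpec("proposed")
        r1 = run_strategy(bundle, spec, _fast_rf(), seed=5, known_noise=truth.true_shift)
        r2 = run_strategy(bundle, spec, _fast_rf(), seed=5, known_noise=truth.true_shift)
        assert r1.cv_auc == r2.cv_auc
        assert r1.test_aucs == r2.test_aucs
        assert r1.aee == pytest.approx(abs(r1.cv_auc - r1.min_test_auc))
        assert 0.0 <= r1.cv_auc <= 1.0
        assert [i for i, _, _ in r1.top_importances][:5] == [
            i for i, _, _ in r2.top_importances
        ][:5]

    def test_filtering_reduces_feature_count(self, tiny_bundle):
        bundle, _ = tiny_bundle
        r = run_strategy(
            bundle, StrategySpec("filtering", filter_method="ccc"), _fast_rf(), seed=1
        )
        assert 0 < r.n_features_used < bundle.main.n_features

    def test_oracle_needs_extra_pool(self, tiny_bundle):
        bundle, _ = tiny_bundle
        stripped = StudyBundle(side=bundle.side, main=bundle.main,
                               test_groups=bundle.test_groups)
        with pytest.raises(ValueError, match="oracle"):
            run_strategy(stripped, StrategySpec("oracle"), _fast_rf(), seed=1)

    def test_empty_stable_set_is_an_error(self, tiny_bundle, rng):
        bundle, _ = tiny_bundle
        # side study where every feature disagrees wildly -> all removed
        from dafit import FeatureTable, SideStudy

        a = bundle.side.a
        b = FeatureTable(
            values=a.values + rng.normal(scale=1000.0, size=a.values.shape),
            feature_names=a.feature_names,
        )
        broken = StudyBundle(
            side=SideStudy(mode="paired", a=a, b=b),
            main=bundle.main, test_groups=bundle.test_groups,
        )
        with pytest.raises(AllFeaturesRemovedError):
            run_strategy(broken, StrategySpec("filtering", filter_method="ccc"),
                         _fast_rf(), seed=1)

    def test_label_permutation_drives_auc_to_chance(self, tiny_bundle, rng):
        bundle, truth = tiny_bundle
        shuffled = FeatureTable(
            values=bundle.main.values,
            feature_names=bundle.main.feature_names,
            labels=rng.permutation(bundle.main.labels),
        )
        null_bundle = StudyBundle(side=bundle.side, main=shuffled,
                                  test_groups=bundle.test_groups)
        r = run_strategy(null_bundle, StrategySpec("simple"), _fast_rf(), seed=2)
        assert abs(r.cv_auc - 0.5) < 0.12  # tiny n: generous band

    def test_fold_training_sizes_exclude_held_out_rows(self, tiny_bundle, caplog):
        """Augmentation doubles only the fold-training rows; held-out rows
        never enter the processed training set."""
        bundle, truth = tiny_bundle
        m = bundle.main.n_observations
        with caplog.at_level(logging.DEBUG, logger="dafit.evaluation"):
            run_strategy(bundle, StrategySpec("proposed"), _fast_rf(),
                         seed=3, known_noise=truth.true_shift)
        fold_logs = [r for r in caplog.records if "held out" in r.message]
        assert len(fold_logs) == 5
        for rec in fold_logs:
            _, n_proc, n_before, n_held = rec.args
            assert n_before + n_held == m
            assert n_proc == 2 * n_before  # two copies per original, no originals

    def test_combined_filters_then_augments(self, tiny_bundle):
        bundle, truth = tiny_bundle
        r = run_strategy(
            bundle, StrategySpec("combined", filter_method="ccc"), _fast_rf(),
            seed=4, known_noise=truth.true_shift,
        )
        assert r.n_features_used < bundle.main.n_features
        assert not r.failed


class TestRunExperiment:
    def test_row_count_and_determinism(self, tiny_benchmark_cfg):
        strats = [StrategySpec("simple"), StrategySpec("proposed")]
        res1 = run_experiment(tiny_benchmark_cfg, strats, [_fast_rf()],
                              n_repeats=3, base_seed=11, use_known_noise=True)
        res2 = run_experiment(tiny_benchmark_cfg, strats, [_fast_rf()],
                              n_repeats=3, base_seed=11, use_known_noise=True)
        assert len(res1.records) == 6
        assert res1.table.drop(columns="failure_reason").equals(
            res2.table.drop(columns="failure_reason")
        )

    def test_failed_runs_are_flagged_rows(self, tiny_benchmark_cfg):
        """A filter that removes every feature yields a flagged row, not a crash."""
        strict = StrategySpec(
            "filtering", filter_method="ccc",
        )
        strict.filter_config.tau_ccc = 1.0  # nothing survives exact agreement
        res = run_experiment(tiny_benchmark_cfg, [strict], [_fast_rf()],
                             n_repeats=1, base_seed=0)
        assert res.table["failed"].all()
        assert "removed all features" in res.table["failure_reason"].iloc[0]

    def test_summary_has_bootstrap_intervals(self, tiny_benchmark_cfg):
        res = run_experiment(tiny_benchmark_cfg, [StrategySpec("simple")],
                             [_fast_rf()], n_repeats=3, base_seed=1)
        summary = res.summary(n_boot=200, seed=0)
        assert summary.loc[0, "aee_ci_lo"] <= summary.loc[0, "mean_aee"]
        assert summary.loc[0, "mean_aee"] <= summary.loc[0, "aee_ci_hi"]
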