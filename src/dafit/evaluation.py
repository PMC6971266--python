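"""Benchmarking harness: strategies, classifiers, nested CV, AUC and AEE.

Compares strategies for handling side-study stability information:

* ``oracle``    — train on a pool that already contains the confounder
                  variation (upper-bound reference);
* ``simple``    — ignore the side study entirely;
* ``filtering`` — drop features the side study flags as unstable;
* ``proposed``  — augment the training rows with the side study's noise
                  model (information transfer);
* ``combined``  — filter first, then augment the surviving features.

Any strategy can additionally be SMOTE-oversampled so its training set
matches the augmented set's size (the sample-size control).

Per run: stratified outer cross-validation estimates the performance a
practitioner would report (``cv_auc``); the model refit on the full pool is
then scored on each confounder-shifted test group, and the absolute
estimation error AEE = |cv_auc - min(test group AUCs)| measures how far the
reported estimate is from the worst deployment performance.

Fold hygiene: the stable set and the noise model come from the side study
only; augmentation and SMOTE are applied inside each outer fold's training
part, never to held-out rows.  All randomness is derived from the run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .augmentation import AugmentConfig, dafit_augment, smote_oversample
from .data_model import FeatureTable, StudyBundle
from .noise import NoiseModel, estimate_noise
from .stability import FilterConfig, StableSet, ccc_filter, ttest_filter
from .synthetic import BenchmarkConfig, BenchmarkTruth, generate_bundle

logger = logging.getLogger(__name__)

__all__ = [
    "StrategySpec",
    "ClassifierSpec",
    "StrategyResult",
    "ExperimentResult",
    "AllFeaturesRemovedError",
    "auc",
    "run_strategy",
    "run_experiment",
    "bootstrap_ci",
    "importance_overlap",
]

STRATEGY_NAMES = ("oracle", "simple", "filtering", "proposed", "combined")


class AllFeaturesRemovedError(RuntimeError):
    """Raised when the stability filter leaves no feature to train on."""


@dataclass
class StrategySpec:
    """A named strategy plus its filter/augmentation settings.

    ``smote`` grows the processed training set by convex same-class
    interpolation until it matches the size the augmentation transform
    would have produced — isolating sample-count effects from information
    transfer.
    """

    name: str
    filter_method: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    smote: bool = False

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.name in ("filtering", "combined") and self.filter_method is None:
            raise ValueError(f"strategy {self.name!r} requires filter_method")
        if self.filter_method not in (None, "ccc", "ttest"):
            raise ValueError(f"unknown filter_method {self.filter_method!r}")

    @property
    def uses_filter(self) -> bool:
        return self.name in ("filtering", "combined")

    @property
    def uses_augment(self) -> bool:
        return self.name in ("proposed", "combined")

    @property
    def label(self) -> str:
        return self.name + ("+smote" if self.smote else "")


#: default tuning grids; deliberately small, documented here rather than
#: hidden in code.  `params` in ClassifierSpec overrides fixed settings,
#: `tuning_grid` overrides the grid.
_DEFAULT_GRIDS = {
    "random_forest": {"max_features": ["sqrt", 0.1], "min_samples_leaf": [1, 5]},
    "gradient_boosting": {
        "n_estimators": [100, 300],
        "learning_rate": [0.05, 0.1],
        "max_depth": [2, 3],
    },
    "lasso_logistic": {"model__C": list(np.logspace(-3, 2, 10))},
}


@dataclass
class ClassifierSpec:
    """A classifier family with its hyperparameter tuning grid.

    kind : ``random_forest``, ``gradient_boosting`` or ``lasso_logistic``.
    tuning_grid : grid searched by the inner CV (None -> documented default).
    params : fixed constructor overrides (e.g. fewer trees for quick runs).
    inner_folds : folds of the inner tuning CV (default 3).
    """

    kind: str
    tuning_grid: dict | None = None
    params: dict = field(default_factory=dict)
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if self.kind not in _DEFAULT_GRIDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    @property
    def grid(self) -> dict:
        g = self.tuning_grid if self.tuning_grid is not None else _DEFAULT_GRIDS[self.kind]
        if not g:
            raise ValueError("tuning grid must be non-empty")
        return g

    def build(self, random_state: int):
        if self.kind == "random_forest":
            kwargs = {"n_estimators": 500, "n_jobs": 1, **self.params}
            return RandomForestClassifier(random_state=random_state, **kwargs)
        if self.kind == "gradient_boosting":
            return GradientBoostingClassifier(random_state=random_state, **self.params)
        # LASSO: L1-penalised logistic regression; features standardised on
        # the training rows only (penalised coefficients need a common scale;
        # tree models above use raw features).
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "model",
                    LogisticRegression(
                        penalty="l1", solver="liblinear", max_iter=5000,
                        random_state=random_state, **self.params,
                    ),
                ),
            ]
        )


@dataclass
class StrategyResult:
    """Outcome of one strategy x classifier run."""

    strategy: str
    classifier: str
    cv_auc: float
    test_aucs: list[float]
    min_test_auc: float
    aee: float
    n_features_used: int
    top_importances: list[tuple[int, str, float]]  # (original index, name, score)
    repeat_index: int = 0
    seed: int = 0
    failed: bool = False
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.failed:
            assert abs(self.aee - abs(self.cv_auc - self.min_test_auc)) < 1e-12
            for v in (self.cv_auc, self.min_test_auc, *self.test_aucs):
                assert 0.0 <= v <= 1.0


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, scores))


def bootstrap_ci(
    values: np.ndarray, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def _extract_importances(estimator) -> np.ndarray:
    if isinstance(estimator, Pipeline):
        return np.abs(np.ravel(estimator.named_steps["model"].coef_))
    return np.asarray(estimator.feature_importances_, dtype=float)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def _stable_set(bundle: StudyBundle, strategy: StrategySpec) -> StableSet | None:
    if not strategy.uses_filter:
        return None
    if strategy.filter_method == "ccc":
        stable = ccc_filter(bundle.side, strategy.filter_config)
    else:
        stable = ttest_filter(bundle.side, strategy.filter_config)
    if stable.n_kept == 0:
        raise AllFeaturesRemovedError(
            f"{strategy.filter_method} filter removed all features"
        )
    return stable


def _process_training(
    X: np.ndarray,
    y: np.ndarray,
    strategy: StrategySpec,
    noise: NoiseModel | None,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply augmentation and/or SMOTE to one fold's training rows.

    Feature filtering has already been applied as a column subset upstream;
    ``noise`` is already restricted to the same columns.
    """
    names = [str(j) for j in range(X.shape[1])]
    table = FeatureTable(values=X, feature_names=names, labels=y)
    k = strategy.augment.copies_per_observation
    if strategy.uses_augment:
        cfg = AugmentConfig(
            copies_per_observation=k,
            include_originals=strategy.augment.include_originals,
            seed=seed,
        )
        table = dafit_augment(table, noise, cfg)
    if strategy.smote:
        # match the size the augmentation transform would produce: each
        # class grows by (k - 1) x its current count, with k >= 2
        factor = max(k, 2) - 1
        counts = {
            int(c): int(np.sum(table.labels == c)) * factor
            for c in np.unique(table.labels)
        }
        table = smote_oversample(table, counts, seed=seed + 1)
    return table.values, table.labels


def run_strategy(
    bundle: StudyBundle,
    strategy: StrategySpec,
    clf: ClassifierSpec,
    outer_folds: int = 5,
    seed: int = 0,
    known_noise: NoiseModel | None = None,
    repeat_index: int = 0,
) -> StrategyResult:
    """Run one strategy with one classifier on a study bundle.

    Outer stratified CV on the training pool estimates ``cv_auc`` (the
    strategy's processing is applied to each fold's training part only);
    the model refit on the full processed pool is scored on every test
    group.  ``known_noise`` substitutes the ground-truth noise model for
    the side-study estimate (simulation studies only).
    """
    if strategy.name == "oracle":
        if bundle.oracle_extra is None:
            raise ValueError("oracle strategy requires bundle.oracle_extra")
        X = np.vstack([bundle.main.values, bundle.oracle_extra.values])
        y = np.concatenate([bundle.main.labels, bundle.oracle_extra.labels])
    else:
        X, y = bundle.main.values, bundle.main.labels

    stable = _stable_set(bundle, strategy)
    feature_idx = (
        stable.kept if stable is not None else np.arange(X.shape[1])
    )
    X = X[:, feature_idx]

    noise = None
    if strategy.uses_augment:
        noise = known_noise if known_noise is not None else estimate_noise(bundle.side)
        noise = noise.select_features(feature_idx)

    seeds = _child_seeds(seed, 3 + 2 * outer_folds)
    outer_seed, inner_seed, final_seed = seeds[0], seeds[1], seeds[2]
    fold_seeds = seeds[3:]

    def fit_tuned(X_tr, y_tr, rs):
        est = clf.build(random_state=rs)
        grid = clf.grid
        n_combos = int(np.prod([len(v) for v in grid.values()]))
        if n_combos == 1:
            est.set_params(**{k: v[0] for k, v in grid.items()})
            est.fit(X_tr, y_tr)
            return est
        inner = StratifiedKFold(clf.inner_folds, shuffle=True, random_state=inner_seed)
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=inner, n_jobs=1)
        search.fit(X_tr, y_tr)
        return search.best_estimator_

    outer = StratifiedKFold(outer_folds, shuffle=True, random_state=outer_seed)
    fold_aucs = []
    for f, (tr, te) in enumerate(outer.split(X, y)):
        X_tr, y_tr = _process_training(
            X[tr], y[tr], strategy, noise, seed=fold_seeds[2 * f]
        )
        logger.debug(
            "fold %d: %d training rows (%d before processing), %d held out",
            f, len(y_tr), len(tr), len(te),
        )
        model = fit_tuned(X_tr, y_tr, rs=fold_seeds[2 * f + 1])
        X_te = X[te]
        if strategy.uses_augment:
            # an augmenting strategy's practitioner cross-validates the
            # augmented dataset, so held-out observations carry a noise draw
            # too; one fresh draw per held-out row keeps the estimate
            # leak-free (no shared parent rows between train and held-out)
            # while estimating performance under the confounded condition.
            hrng = np.random.default_rng(fold_seeds[2 * f] + 1)
            X_te = X_te + noise.mu + hrng.standard_normal(X_te.shape) * np.sqrt(noise.sigma2)
        fold_aucs.append(auc(model.predict_proba(X_te)[:, 1], y[te]))
    cv_auc = float(np.mean(fold_aucs))

    X_full, y_full = _process_training(X, y, strategy, noise, seed=final_seed)
    final = fit_tuned(X_full, y_full, rs=seeds[2] + 1)
    test_aucs = [
        auc(final.predict_proba(g.values[:, feature_idx])[:, 1], g.labels)
        for g in bundle.test_groups
    ]
    min_test = float(min(test_aucs))

    imp = _extract_importances(final)
    order = np.argsort(-imp, kind="stable")
    names = bundle.feature_names
    top = [
        (int(feature_idx[i]), names[feature_idx[i]], float(imp[i])) for i in order
    ]

    return StrategyResult(
        strategy=strategy.label,
        classifier=clf.kind,
        cv_auc=cv_auc,
        test_aucs=[float(v) for v in test_aucs],
        min_test_auc=min_test,
        aee=abs(cv_auc - min_test),
        n_features_used=int(feature_idx.size),
        top_importances=top,
        repeat_index=repeat_index,
        seed=seed,
    )


@dataclass
class ExperimentResult:
    """Results of a repeated strategy x classifier experiment."""

    records: list[StrategyResult]
    truths: list[BenchmarkTruth | None]

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": r.strategy,
                "classifier": r.classifier,
                "repeat": r.repeat_index,
                "cv_auc": r.cv_auc,
                "min_test_auc": r.min_test_auc,
                "aee": r.aee,
                "n_features_used": r.n_features_used,
                "failed": r.failed,
                "failure_reason": r.failure_reason,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def summary(self, n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
        """Mean AUC/AEE per strategy x classifier with bootstrap 95% CIs."""
        df = self.table[~self.table["failed"]]
        out = []
        for (s, c), grp in df.groupby(["strategy", "classifier"], sort=False):
            row = {"strategy": s, "classifier": c, "n_runs": len(grp)}
            for col in ("cv_auc", "min_test_auc", "aee"):
                vals = grp[col].to_numpy()
                row[f"mean_{col}"] = float(vals.mean())
                if vals.size >= 2:
                    lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=seed)
                    row[f"{col}_ci_lo"], row[f"{col}_ci_hi"] = lo, hi
            out.append(row)
        return pd.DataFrame(out)


def run_experiment(
    source: StudyBundle | BenchmarkConfig,
    strategies: list[StrategySpec],
    classifiers: list[ClassifierSpec],
    n_repeats: int = 10,
    base_seed: int = 0,
    outer_folds: int = 5,
    n_side_subjects: int = 30,
    use_known_noise: bool = False,
) -> ExperimentResult:
    """Cartesian product strategy x classifier x repeat.

    Given a ``BenchmarkConfig``, a fresh benchmark and side study are drawn
    per repeat (seeded from ``base_seed``); given a fixed ``StudyBundle``,
    only the CV/augmentation randomness varies across repeats.  Failed runs
    (e.g. a filter removing every feature) are reported as flagged rows.
    """
    records: list[StrategyResult] = []
    truths: list[BenchmarkTruth | None] = []
    repeat_seeds = _child_seeds(base_seed, 2 * n_repeats)
    for rep in range(n_repeats):
        data_seed, run_seed = repeat_seeds[2 * rep], repeat_seeds[2 * rep + 1]
        if isinstance(source, BenchmarkConfig):
            bundle, truth = generate_bundle(
                source, n_side_subjects=n_side_subjects, seed=data_seed
            )
            known = truth.true_shift if use_known_noise else None
        else:
            bundle, truth, known = source, None, None
        truths.append(truth)
        for strategy in strategies:
            for clf in classifiers:
                try:
                    rec = run_strategy(
                        bundle, strategy, clf, outer_folds=outer_folds,
                        seed=run_seed, known_noise=known, repeat_index=rep,
                    )
                except AllFeaturesRemovedError as err:
                    logger.warning("run failed (%s/%s): %s",
                                   strategy.label, clf.kind, err)
                    rec = StrategyResult(
                        strategy=strategy.label, classifier=clf.kind,
                        cv_auc=float("nan"), test_aucs=[],
                        min_test_auc=float("nan"), aee=float("nan"),
                        n_features_used=0, top_importances=[],
                        repeat_index=rep, seed=run_seed,
                        failed=True, failure_reason=str(err),
                    )
                records.append(rec)
    return ExperimentResult(records=records, truths=truths)


def importance_overlap(
    result: StrategyResult, truth: BenchmarkTruth, top_k: int = 20
) -> dict[str, int]:
    """How well a model's importance ranking recovers the informative features.

    Returns the number of truly informative features among the ``top_k``
    most important ones, and the length of the leading run of the ranking
    consisting only of informative features.
    """
    if top_k > len(result.top_importances):
        raise ValueError("top_k exceeds the number of ranked features")
    informative = set(int(i) for i in truth.informative)
    ranked = [idx for idx, _, _ in result.top_importances]
    n_top = sum(1 for idx in ranked[:top_k] if idx in informative)
    prefix = 0
    for idx in ranked:
        if idx in informative:
            prefix += 1
        else:
            break
    return {"n_meaningful_in_top_k": n_top, "prefix_meaningful": prefix}
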