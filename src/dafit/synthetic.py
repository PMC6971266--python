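"""Synthetic confounded benchmark with known ground truth.

Emulates a high-dimensional two-class biomarker study in which a confounder
(scanner, rater, acquisition protocol) shifts every feature of the test
cohort relative to the training cohort:

* per feature j, a base distribution N(m_j, s_j^2) with m_j and s_j drawn
  uniformly from configurable ranges;
* a small subset of "informative" features whose class-1 mean is displaced
  by ``effect_size`` base standard deviations;
* a training set acquired under a single confounder value (no shift);
* a test set acquired under a different confounder value: each feature is
  shifted by a systematic per-feature offset delta_j (drawn once) plus
  per-observation noise with a per-feature standard deviation;
* a paired side study measuring confounder-free subjects under both
  conditions, drawn from the same noise model — the ground truth
  (delta_j, sigma_j^2) is recorded so estimators can be checked against it.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import FeatureTable, SideStudy, StudyBundle
from .noise import NoiseModel

__all__ = [
    "BenchmarkConfig",
    "BenchmarkTruth",
    "generate_benchmark",
    "generate_side_study",
    "generate_oracle_extra",
    "generate_bundle",
]


@dataclass
class BenchmarkConfig:
    """Generator settings; defaults emulate a typical high-dimensional study.

    n_features / n_informative : 4000 features of which 20 separate the
        classes.
    n_train_per_class / n_test_per_class : 150 training and 500 test
        observations per class (the test set is larger to stabilise the
        evaluation).
    feature_mean_range / feature_sd_range : hyper-ranges for the per-feature
        base distributions.
    effect_size : class-1 mean displacement of informative features, in
        units of the feature's base standard deviation.
    shift_mu_sd : standard deviation of the systematic per-feature test-set
        shift delta_j (0 disables the confounder).
    shift_sigma_range : range the per-feature observation-noise standard
        deviation sigma_j is drawn from.
    noise_family : ``normal`` or ``skew_normal`` (stress test; with
        ``skew_alpha`` = 0 the skew-normal family reduces to the normal one).
    """

    n_features: int = 4000
    n_informative: int = 20
    n_train_per_class: int = 150
    n_test_per_class: int = 500
    feature_mean_range: tuple[float, float] = (-1.0, 1.0)
    feature_sd_range: tuple[float, float] = (0.5, 2.0)
    effect_size: float = 1.0
    shift_mu_sd: float = 1.0
    shift_sigma_range: tuple[float, float] = (0.0, 1.0)
    noise_family: str = "normal"
    skew_alpha: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("need 0 <= n_informative <= n_features")
        if self.n_train_per_class < 1 or self.n_test_per_class < 1:
            raise ValueError("per-class sample counts must be >= 1")
        for lo, hi in (self.feature_mean_range, self.feature_sd_range,
                       self.shift_sigma_range):
            if lo > hi:
                raise ValueError("ranges must satisfy lo <= hi")
        if self.feature_sd_range[0] <= 0:
            raise ValueError("feature sds must be positive")
        if self.shift_mu_sd < 0 or self.shift_sigma_range[0] < 0:
            raise ValueError("shift scales must be non-negative")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise_family not in ("normal", "skew_normal"):
            raise ValueError(f"unknown noise_family {self.noise_family!r}")


@dataclass
class BenchmarkTruth:
    """Ground truth of a generated benchmark.

    ``informative`` are the indices of the class-separating features;
    ``true_shift`` is the generating confounder noise model (systematic
    shift delta_j as mu, observation-noise variance sigma_j^2 as sigma2);
    the base per-feature means and sds are kept so side studies and oracle
    pools can be drawn from the same population.
    """

    informative: np.ndarray
    true_shift: NoiseModel
    base_mean: np.ndarray
    base_sd: np.ndarray

    def __post_init__(self) -> None:
        self.informative = np.asarray(self.informative, dtype=int)
        n = self.true_shift.n_features
        if self.informative.size and (
            self.informative.min() < 0 or self.informative.max() >= n
        ):
            raise ValueError("informative indices out of range")


def _feature_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"f{j:0{width}d}" for j in range(n)]


def _draw_noise(
    rng: np.random.Generator, family: str, alpha: float, scale, size
) -> np.ndarray:
    """Draw confounder noise from the configured family (location 0 scale given)."""
    if family == "normal" or alpha == 0.0:
        return rng.normal(0.0, scale, size=size)
    return stats.skewnorm.rvs(alpha, loc=0.0, scale=scale, size=size, random_state=rng)


def _class_means(cfg: BenchmarkConfig, truth_mean, truth_sd, informative):
    mean1 = truth_mean.copy()
    mean1[informative] += cfg.effect_size * truth_sd[informative]
    return truth_mean, mean1


def _draw_class_table(
    rng: np.random.Generator,
    cfg: BenchmarkConfig,
    mean0: np.ndarray,
    mean1: np.ndarray,
    sd: np.ndarray,
    n_per_class: int,
    confounder: str,
) -> FeatureTable:
    n = cfg.n_features
    x0 = mean0 + rng.standard_normal((n_per_class, n)) * sd
    x1 = mean1 + rng.standard_normal((n_per_class, n)) * sd
    values = np.vstack([x0, x1])
    labels = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    return FeatureTable(
        values=values,
        feature_names=_feature_names(n),
        labels=labels,
        confounder=np.full(2 * n_per_class, confounder),
    )


def generate_benchmark(cfg: BenchmarkConfig) -> dict:
    """Generate the confounded train/test benchmark.

    Returns ``{"train": FeatureTable, "test": FeatureTable,
    "truth": BenchmarkTruth}``.  The training set has no confounder shift;
    every test-set feature is shifted by delta_j ~ N(0, shift_mu_sd^2)
    (drawn once per feature) plus per-observation noise of standard
    deviation sigma_j ~ Uniform(shift_sigma_range).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_features
    base_mean = rng.uniform(*cfg.feature_mean_range, size=n)
    base_sd = rng.uniform(*cfg.feature_sd_range, size=n)
    informative = np.sort(rng.choice(n, size=cfg.n_informative, replace=False))
    mean0, mean1 = _class_means(cfg, base_mean, base_sd, informative)

    train = _draw_class_table(rng, cfg, mean0, mean1, base_sd,
                              cfg.n_train_per_class, confounder="v1")

    delta = _draw_noise(rng, cfg.noise_family, cfg.skew_alpha, cfg.shift_mu_sd, n)
    if cfg.shift_mu_sd == 0.0:
        delta = np.zeros(n)
    shift_sigma = rng.uniform(*cfg.shift_sigma_range, size=n)

    test = _draw_class_table(rng, cfg, mean0, mean1, base_sd,
                             cfg.n_test_per_class, confounder="v2")
    obs_noise = _draw_noise(
        rng, cfg.noise_family, cfg.skew_alpha, shift_sigma, test.values.shape
    )
    test.values = test.values + delta + obs_noise

    truth = BenchmarkTruth(
        informative=informative,
        true_shift=NoiseModel(
            mu=delta,
            sigma2=shift_sigma**2,
            source_mode="known",
            feature_names=list(train.feature_names),
        ),
        base_mean=base_mean,
        base_sd=base_sd,
    )
    return {"train": train, "test": test, "truth": truth}


def generate_side_study(
    truth: BenchmarkTruth, cfg: BenchmarkConfig, n_subjects: int, seed: int
) -> SideStudy:
    """Draw a paired side study from the benchmark's noise model.

    ``n_subjects`` class-0 subjects are measured twice: measurement ``a``
    under the training condition, measurement ``b`` under the shifted
    condition (a plus per-feature noise from ``truth.true_shift``).  No
    labels are attached — a side study carries confounder information, not
    target information.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 side-study subjects")
    rng = np.random.default_rng(seed)
    n = truth.true_shift.n_features
    base = truth.base_mean + rng.standard_normal((n_subjects, n)) * truth.base_sd
    noise = truth.true_shift.mu + _draw_noise(
        rng, cfg.noise_family, cfg.skew_alpha,
        np.sqrt(truth.true_shift.sigma2), (n_subjects, n),
    )
    names = _feature_names(n)
    return SideStudy(
        mode="paired",
        a=FeatureTable(values=base, feature_names=names),
        b=FeatureTable(values=base + noise, feature_names=names),
    )


def generate_oracle_extra(
    truth: BenchmarkTruth, cfg: BenchmarkConfig, n_per_class: int, seed: int
) -> FeatureTable:
    """Labelled extra training rows acquired under the *shifted* condition.

    Pooling these with the unshifted training set gives a training pool that
    contains the confounder variation — the oracle strategy's advantage.
    """
    rng = np.random.default_rng(seed)
    informative = truth.informative
    mean0, mean1 = _class_means(cfg, truth.base_mean, truth.base_sd, informative)
    table = _draw_class_table(rng, cfg, mean0, mean1, truth.base_sd,
                              n_per_class, confounder="v2")
    obs_noise = _draw_noise(
        rng, cfg.noise_family, cfg.skew_alpha,
        np.sqrt(truth.true_shift.sigma2), table.values.shape,
    )
    table.values = table.values + truth.true_shift.mu + obs_noise
    return table


def generate_bundle(
    cfg: BenchmarkConfig,
    n_side_subjects: int = 30,
    n_oracle_per_class: int | None = None,
    seed: int | None = None,
) -> tuple[StudyBundle, BenchmarkTruth]:
    """Generate a complete study bundle (side, main, oracle pool, test group).

    ``seed`` defaults to ``cfg.seed``; side study and oracle pool use child
    seeds derived from it so the pieces are independent but reproducible.
    """
    if seed is not None:
        cfg = BenchmarkConfig(**{**cfg.__dict__, "seed": seed})
    bench = generate_benchmark(cfg)
    children = np.random.SeedSequence(cfg.seed).spawn(2)
    side_seed = int(children[0].generate_state(1)[0] % (2**31))
    oracle_seed = int(children[1].generate_state(1)[0] % (2**31))
    side = generate_side_study(bench["truth"], cfg, n_side_subjects, side_seed)
    n_oracle = (
        cfg.n_train_per_class if n_oracle_per_class is None else n_oracle_per_class
    )
    extra = generate_oracle_extra(bench["truth"], cfg, n_oracle, oracle_seed)
    bundle = StudyBundle(
        side=side,
        main=bench["train"],
        oracle_extra=extra,
        test_groups=[bench["test"]],
    )
    return bundle, bench["truth"]
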