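import numpy as np
import pytest

from dafit import BenchmarkConfig, FeatureTable, SideStudy


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture()
def small_table(rng):
    """A 12-row, 5-feature labelled table."""
    values = rng.normal(size=(12, 5))
    return FeatureTable(
        values=values,
        feature_names=[f"f{j}" for j in range(5)],
        labels=np.array([0, 1] * 6),
    )


@pytest.fixture()
def paired_side(rng):
    """A paired side study with per-feature shift and noise."""
    n, p = 40, 6
    base = rng.normal(size=(n, p))
    mu = np.array([0.0, 1.0, -0.5, 0.0, 2.0, 0.2])
    sd = np.array([0.1, 0.5, 0.2, 0.0, 1.0, 0.3])
    names = [f"f{j}" for j in range(p)]
    a = FeatureTable(values=base, feature_names=names)
    b = FeatureTable(values=base + mu + rng.normal(size=(n, p)) * sd, feature_names=names)
    return SideStudy(mode="paired", a=a, b=b)


@pytest.fixture()
def tiny_benchmark_cfg():
    """A benchmark small enough for fast end-to-end runs."""
    return BenchmarkConfig(
        n_features=120,
        n_informative=10,
        n_train_per_class=30,
        n_test_per_class=50,
        seed=42,
    )
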