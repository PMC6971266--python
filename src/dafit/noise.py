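"""Per-feature confounder noise models estimated from a side study.

The confounder's influence on each feature j is modelled as additive
Gaussian noise N(mu_j, sigma2_j).  The noise model is the object that
carries information from the side study into the main study: it is
estimated once from the side experiment and then used to augment the main
study's observations.

Paired side study (same subjects measured under both confounder values):
mu and sigma2 are the mean and sample variance of the per-subject
differences (group b minus group a).

Unpaired side study (two cohorts split by confounder value): mu is the
difference of the group means, and sigma2 is the sum of the two group
variances — the variance of a difference of independent measurements
(Bienaymé).  Note this estimator deliberately accumulates the within-group
variance of both cohorts, so it is inflated relative to the paired one;
that is a property of the estimator, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SideStudy

__all__ = [
    "NoiseModel",
    "estimate_noise_paired",
    "estimate_noise_unpaired",
    "estimate_noise",
    "read_noise_model",
    "write_noise_model",
]


@dataclass
class NoiseModel:
    """Per-feature additive noise N(mu_j, sigma2_j) attributed to the confounder.

    ``mu`` is in feature units (signed: the direction of group b relative to
    group a in the source side study); ``sigma2`` in squared feature units.
    ``source_mode`` records how the model was obtained: ``paired``,
    ``unpaired`` or ``known`` (ground truth injected in simulations).
    """

    mu: np.ndarray
    sigma2: np.ndarray
    source_mode: str
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma2 must be 1-D vectors of equal length")
        if np.any(self.sigma2 < 0):
            raise ValueError("sigma2 must be non-negative")
        if self.source_mode not in ("paired", "unpaired", "known"):
            raise ValueError(f"unknown source_mode {self.source_mode!r}")
        if self.feature_names is not None and len(self.feature_names) != self.mu.size:
            raise ValueError("feature_names length mismatch")

    @property
    def n_features(self) -> int:
        return int(self.mu.size)

    def symmetrized(self) -> "NoiseModel":
        """Copy with mu zeroed, keeping only the variance component.

        Useful when the sign convention (which confounder value the main
        study was acquired under) is unknown or irrelevant.
        """
        return NoiseModel(
            mu=np.zeros_like(self.mu),
            sigma2=self.sigma2.copy(),
            source_mode=self.source_mode,
            feature_names=None if self.feature_names is None else list(self.feature_names),
        )

    def select_features(self, indices: np.ndarray) -> "NoiseModel":
        indices = np.asarray(indices, dtype=int)
        return NoiseModel(
            mu=self.mu[indices],
            sigma2=self.sigma2[indices],
            source_mode=self.source_mode,
            feature_names=None
            if self.feature_names is None
            else [self.feature_names[i] for i in indices],
        )


def estimate_noise_paired(side: SideStudy) -> NoiseModel:
    """Estimate the noise model from paired measurements.

    Per feature j, with differences d_j = b[:, j] - a[:, j]:
    mu_j = mean(d_j) and sigma2_j = sample variance of d_j (ddof=1).
    """
    if side.mode != "paired":
        raise ValueError("estimate_noise_paired requires a paired side study")
    if side.a.n_observations < 2:
        raise ValueError("need at least 2 pairs")
    d = side.b.values - side.a.values
    return NoiseModel(
        mu=d.mean(axis=0),
        sigma2=d.var(axis=0, ddof=1),
        source_mode="paired",
        feature_names=list(side.feature_names),
    )


def estimate_noise_unpaired(side: SideStudy) -> NoiseModel:
    """Estimate the noise model from two unpaired groups.

    mu_j = mean(b[:, j]) - mean(a[:, j]); sigma2_j = var(a[:, j]) +
    var(b[:, j]) with sample (ddof=1) variances, per the Bienaymé sum for
    independent groups.
    """
    if side.mode != "unpaired":
        raise ValueError("estimate_noise_unpaired requires an unpaired side study")
    if side.a.n_observations < 2 or side.b.n_observations < 2:
        raise ValueError("each group needs at least 2 rows")
    a, b = side.a.values, side.b.values
    return NoiseModel(
        mu=b.mean(axis=0) - a.mean(axis=0),
        sigma2=a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1),
        source_mode="unpaired",
        feature_names=list(side.feature_names),
    )


def estimate_noise(side: SideStudy) -> NoiseModel:
    """Dispatch to the paired or unpaired estimator by side-study mode."""
    if side.mode == "paired":
        return estimate_noise_paired(side)
    return estimate_noise_unpaired(side)


def write_noise_model(model: NoiseModel, path: str) -> None:
    """Write a noise model as CSV with columns feature, mu, sigma2."""
    names = model.feature_names or [f"f{j}" for j in range(model.n_features)]
    pd.DataFrame({"feature": names, "mu": model.mu, "sigma2": model.sigma2}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_noise_model(path: str, source_mode: str = "known") -> NoiseModel:
    df = pd.read_csv(path)
    for col in ("feature", "mu", "sigma2"):
        if col not in df.columns:
            raise ValueError(f"{path}: noise model is missing column {col!r}")
    return NoiseModel(
        mu=df["mu"].to_numpy(float),
        sigma2=df["sigma2"].to_numpy(float),
        source_mode=source_mode,
        feature_names=[str(f) for f in df["feature"]],
    )
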