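"""Feature-stability filters and the normality diagnostic.

The filtering baseline discards features whose measurements disagree across
confounder values in a side study: for paired repeats, Lin's concordance
correlation coefficient (CCC) against a retention threshold ``tau_ccc``;
for two unpaired groups, a two-sided two-sample t-test whose p-value,
*uncorrected* for multiple testing, is compared to ``tau_test`` and used as
a probability threshold rather than a significance test.

The normality diagnostic checks the working assumption of the noise model —
that paired measurement differences are normally distributed — with a
per-feature Shapiro-Wilk test under a Bonferroni-adjusted level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import SideStudy

__all__ = [
    "FilterConfig",
    "StableSet",
    "ccc",
    "ccc_filter",
    "ccc_filter_repeats",
    "ttest_filter",
    "NormalityReport",
    "normality_diagnostic",
]


@dataclass
class FilterConfig:
    """Thresholds of the stability filters.

    tau_ccc : retain a feature when its CCC >= tau_ccc (default 0.8, the
        conventional agreement cut-off in reproducibility studies).
    tau_test : remove a feature when its between-group p-value < tau_test
        (default 0.05), with no multiple-testing correction.
    welch : use Welch's unequal-variance t statistic (default) rather than
        the pooled-variance variant.
    """

    tau_ccc: float = 0.8
    tau_test: float = 0.05
    welch: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_ccc <= 1.0:
            raise ValueError("tau_ccc must be in (0, 1]")
        if not 0.0 < self.tau_test < 1.0:
            raise ValueError("tau_test must be in (0, 1)")


@dataclass
class StableSet:
    """Outcome of a stability filter.

    ``kept`` holds the retained feature indices in their original order;
    ``scores`` holds the per-feature statistic for *all* features (CCC values
    for ``method='ccc'``, p-values for ``method='ttest'``).
    """

    kept: np.ndarray
    scores: np.ndarray
    method: str
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.kept = np.asarray(self.kept, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.kept) <= 0):
            raise ValueError("kept indices must be strictly increasing")
        if self.kept.size and (self.kept[0] < 0 or self.kept[-1] >= self.scores.size):
            raise ValueError("kept indices out of range")

    @property
    def n_kept(self) -> int:
        return int(self.kept.size)


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient between two paired vectors.

    Uses population (1/n) moments, the standard Lin estimator:

        CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

    Ranges over [-1, 1]; 1 means perfect agreement with the identity line.
    Two identical constant vectors return 1 by convention (the only 0/0
    case); constant vectors with different means return 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ccc requires two 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("ccc requires at least 2 observations")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # both constant with equal means: complete agreement
    return float(2.0 * sxy / denom)


def _ccc_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised per-column CCC of two aligned matrices."""
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    da, db = a - ma, b - mb
    sa2 = np.mean(da**2, axis=0)
    sb2 = np.mean(db**2, axis=0)
    sab = np.mean(da * db, axis=0)
    denom = sa2 + sb2 + (ma - mb) ** 2
    out = np.ones_like(denom)  # 0/0 convention: identical constants agree
    nz = denom > 0
    out[nz] = 2.0 * sab[nz] / denom[nz]
    return out


def ccc_filter(side: SideStudy, cfg: FilterConfig | None = None) -> StableSet:
    """Retain features whose paired-measurement CCC is at least ``tau_ccc``."""
    cfg = cfg or FilterConfig()
    if side.mode != "paired":
        raise ValueError("ccc_filter requires a paired side study")
    scores = _ccc_columns(side.a.values, side.b.values)
    kept = np.flatnonzero(scores >= cfg.tau_ccc)
    return StableSet(kept=kept, scores=scores, method="ccc",
                     feature_names=list(side.feature_names))


def ccc_filter_repeats(
    tables: list, cfg: FilterConfig | None = None
) -> StableSet:
    """CCC filter for more than two repeated measurements per subject.

    The per-feature score is the mean CCC over all unordered pairs of
    repeats — a convention for collapsing multi-repeat designs (e.g. four
    annotations per lesion) onto the two-group filter.
    """
    cfg = cfg or FilterConfig()
    if len(tables) < 2:
        raise ValueError("need at least two repeat tables")
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names or t.n_observations != tables[0].n_observations:
            raise ValueError("repeat tables must be aligned with identical features")
    pair_scores = [
        _ccc_columns(tables[i].values, tables[j].values)
        for i in range(len(tables))
        for j in range(i + 1, len(tables))
    ]
    scores = np.mean(pair_scores, axis=0)
    kept = np.flatnonzero(scores >= cfg.tau_ccc)
    return StableSet(kept=kept, scores=scores, method="ccc", feature_names=list(names))


def ttest_filter(side: SideStudy, cfg: FilterConfig | None = None) -> StableSet:
    """Remove features that differ between the two unpaired groups.

    Per feature, a two-sided two-sample t-test (Welch by default) between
    groups ``a`` and ``b``; features with p < ``tau_test`` are removed, with
    no multiple-testing correction.  Degenerate columns are handled
    deterministically: constant and equal in both groups -> p = 1 (kept);
    constant but unequal -> p = 0 (removed).
    """
    cfg = cfg or FilterConfig()
    if side.mode != "unpaired":
        raise ValueError("ttest_filter requires an unpaired side study")
    a, b = side.a.values, side.b.values
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each side-study group needs at least 2 rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=not cfg.welch)
        pvals = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if zero_var.any():
        equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
        pvals[zero_var & equal_means] = 1.0
        pvals[zero_var & ~equal_means] = 0.0
    pvals = np.nan_to_num(pvals, nan=1.0)  # residual degeneracies kept
    kept = np.flatnonzero(pvals >= cfg.tau_test)
    return StableSet(kept=kept, scores=pvals, method="ttest",
                     feature_names=list(side.feature_names))


@dataclass
class NormalityReport:
    """Per-feature Shapiro-Wilk outcome under a Bonferroni-adjusted level."""

    p: np.ndarray
    threshold: float
    normal_not_rejected: np.ndarray

    @property
    def n_not_rejected(self) -> int:
        return int(self.normal_not_rejected.sum())

    @property
    def fraction_not_rejected(self) -> float:
        return float(self.normal_not_rejected.mean())


def normality_diagnostic(differences: np.ndarray, alpha: float = 0.05) -> NormalityReport:
    """Test whether paired measurement differences look normally distributed.

    Runs a Shapiro-Wilk test on each feature column of ``differences``
    (pairs x features) and applies a Bonferroni adjustment: normality is not
    rejected for a feature when its p-value >= alpha / n_features.
    """
    differences = np.asarray(differences, dtype=float)
    if differences.ndim == 1:
        differences = differences[:, None]
    if differences.shape[0] < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 rows")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n_features = differences.shape[1]
    threshold = alpha / n_features
    pvals = np.empty(n_features)
    for j in range(n_features):
        col = differences[:, j]
        if np.ptp(col) == 0:  # constant column: no evidence against normality
            pvals[j] = 1.0
        else:
            pvals[j] = stats.shapiro(col).pvalue
    return NormalityReport(
        p=pvals, threshold=threshold, normal_not_rejected=pvals >= threshold
    )
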