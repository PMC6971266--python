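"""Data augmentation operators.

``dafit_augment`` is the information-transfer transform: each main-study
observation x is replaced by k augmented copies x + e, where e is drawn
per feature from the side-study noise model N(mu_j, sigma2_j).  The
augmented set carries the confounder variability measured in the side
study into the training data, so that embedded feature selection can trade
a feature's informativeness against its instability instead of discarding
it outright.

``smote_oversample`` is the sample-size control: classic SMOTE synthesises
new observations by convex interpolation between same-class nearest
neighbours, adding rows without adding any confounder information.  It is
implemented here (rather than delegated) so that the neighbour rule,
distance metric and random draws are pinned and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data_model import FeatureTable
from .noise import NoiseModel

__all__ = ["AugmentConfig", "dafit_augment", "smote_oversample"]


@dataclass
class AugmentConfig:
    """Settings of the augmentation transform.

    copies_per_observation : number of augmented copies drawn per original
        row (default 2).
    include_originals : also keep the unaugmented rows (default False: the
        augmented observations *replace* the originals).
    seed : RNG seed; the transform is deterministic given the seed.
    """

    copies_per_observation: int = 2
    include_originals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_observation < 1:
            raise ValueError("copies_per_observation must be >= 1")


def dafit_augment(
    main: FeatureTable, noise: NoiseModel, cfg: AugmentConfig | None = None
) -> FeatureTable:
    """Augment a labelled feature table with confounder noise.

    For each original row x_i and each of k copies, emits x_i + e with
    e_j ~ N(mu_j, sigma2_j) drawn independently per feature and per copy;
    the label is copied from the source row.  Output has m*k rows (m*(k+1)
    when ``include_originals``), ordered as k stacked blocks of the input
    rows (originals first when kept).
    """
    cfg = cfg or AugmentConfig()
    if main.labels is None:
        raise ValueError("dafit_augment requires a labelled main study")
    if noise.n_features != main.n_features:
        raise ValueError(
            f"noise model has {noise.n_features} features, table has {main.n_features}"
        )
    rng = np.random.default_rng(cfg.seed)
    sd = np.sqrt(noise.sigma2)
    k = cfg.copies_per_observation
    m, n = main.values.shape

    blocks = []
    for _ in range(k):
        e = noise.mu + rng.standard_normal((m, n)) * sd
        blocks.append(main.values + e)
    values = np.vstack(blocks)
    labels = np.tile(main.labels, k)
    if cfg.include_originals:
        values = np.vstack([main.values, values])
        labels = np.concatenate([main.labels, labels])
    return FeatureTable(values=values, feature_names=list(main.feature_names), labels=labels)


def smote_oversample(
    table: FeatureTable,
    n_synthetic_per_class: dict[int, int],
    k_neighbors: int = 5,
    seed: int = 0,
) -> FeatureTable:
    """Classic SMOTE oversampling on raw feature values.

    For each requested synthetic sample of a class: pick a random member x
    of that class, pick a random neighbour z among its k nearest same-class
    neighbours (Euclidean distance), and emit x + u * (z - x) with
    u ~ Uniform(0, 1).  Output is the original table followed by the
    synthetic rows; deterministic given ``seed``.
    """
    if table.labels is None:
        raise ValueError("smote_oversample requires labels")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng(seed)

    synth_values = []
    synth_labels = []
    for cls, n_new in sorted(n_synthetic_per_class.items()):
        if n_new < 0:
            raise ValueError("synthetic counts must be non-negative")
        if n_new == 0:
            continue
        members = table.values[table.labels == cls]
        if members.shape[0] <= k_neighbors:
            raise ValueError(
                f"class {cls} has {members.shape[0]} members, "
                f"needs more than k_neighbors={k_neighbors}"
            )
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(members)
        # first neighbour is the point itself; keep the k genuine ones
        neigh = nn.kneighbors(members, return_distance=False)[:, 1:]
        parents = rng.integers(0, members.shape[0], size=n_new)
        picks = neigh[parents, rng.integers(0, k_neighbors, size=n_new)]
        u = rng.uniform(0.0, 1.0, size=(n_new, 1))
        x, z = members[parents], members[picks]
        synth_values.append(x + u * (z - x))
        synth_labels.append(np.full(n_new, cls, dtype=int))

    if not synth_values:
        return FeatureTable(
            values=table.values.copy(),
            feature_names=list(table.feature_names),
            labels=table.labels.copy(),
        )
    return FeatureTable(
        values=np.vstack([table.values, *synth_values]),
        feature_names=list(table.feature_names),
        labels=np.concatenate([table.labels, *synth_labels]),
    )
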