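"""Core containers for tabular feature studies.

A *feature table* is a dense (observations x features) real matrix with named
columns, optionally carrying a binary class label and a categorical confounder
value per observation.  A *side study* holds two measurement groups of the
same features acquired under two different confounder values, either paired
(row i of both groups is the same subject) or unpaired.  A *study bundle*
wires together the pieces of a confounded benchmark: the side study, the main
(training) study, an optional extra training pool that already contains the
confounder variation, and one or more confounder-shifted test groups.

Missing values are a hard error throughout: silently imputing a feature cell
would contaminate downstream noise estimation, so malformed input is rejected
at parse time with the offending row and column named.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "SideStudy",
    "StudyBundle",
    "read_feature_table",
    "write_feature_table",
    "read_side_study",
]

#: significant digits preserved by the CSV writer; round-trips are exact to
#: at least 12 significant digits (we write 17, enough for IEEE doubles).
_FLOAT_FORMAT = "%.17g"


@dataclass
class FeatureTable:
    """Dense observations x features matrix with named features.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Feature matrix; no missing values allowed.
    feature_names : list of str
        Unique column names, length n.
    labels : ndarray of shape (m,), optional
        Binary class labels in {0, 1}.
    confounder : ndarray of shape (m,), optional
        Categorical confounder value per observation.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None
    confounder: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("feature table needs at least one row and one feature")
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != n:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {n} columns"
            )
        if len(set(self.feature_names)) != n:
            raise ValueError("feature names must be unique")
        bad = np.argwhere(np.isnan(self.values))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"missing value at row {i}, column {self.feature_names[j]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (m,):
                raise ValueError("labels length must match row count")
            if not set(np.unique(self.labels)) <= {0, 1}:
                raise ValueError("labels must be binary 0/1")
        if self.confounder is not None:
            self.confounder = np.asarray(self.confounder)
            if self.confounder.shape != (m,):
                raise ValueError("confounder length must match row count")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, indices: np.ndarray) -> "FeatureTable":
        """Return a copy restricted to the feature columns ``indices`` (in order)."""
        indices = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[:, indices],
            feature_names=[self.feature_names[i] for i in indices],
            labels=None if self.labels is None else self.labels.copy(),
            confounder=None if self.confounder is None else self.confounder.copy(),
        )

    def subset_rows(self, indices: np.ndarray) -> "FeatureTable":
        indices = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[indices],
            feature_names=list(self.feature_names),
            labels=None if self.labels is None else self.labels[indices],
            confounder=None if self.confounder is None else self.confounder[indices],
        )


@dataclass
class SideStudy:
    """Two measurement groups of the same features under two confounder values.

    ``mode`` is ``"paired"`` when row i of group ``a`` and group ``b`` are the
    same subject measured twice, and ``"unpaired"`` when the groups are
    disjoint cohorts split by confounder value.  Labels on side studies are
    never used: a side experiment quantifies confounder effects, not the
    prediction target.
    """

    mode: str
    a: FeatureTable
    b: FeatureTable

    def __post_init__(self) -> None:
        if self.mode not in ("paired", "unpaired"):
            raise ValueError(f"unknown side-study mode {self.mode!r}")
        if self.a.feature_names != self.b.feature_names:
            raise ValueError("side-study groups must share identical feature names")
        if self.mode == "paired" and self.a.n_observations != self.b.n_observations:
            raise ValueError("paired side study requires equal group sizes")

    @property
    def feature_names(self) -> list[str]:
        return self.a.feature_names

    @property
    def n_features(self) -> int:
        return self.a.n_features


@dataclass
class StudyBundle:
    """The split design of a confounded benchmark.

    ``side`` quantifies the confounder (split A); ``main`` is the labelled
    training study acquired under a single confounder value (group B1);
    ``oracle_extra`` optionally extends the training pool with labelled rows
    that *do* contain the confounder variation (the rest of split B, used by
    the oracle strategy); ``test_groups`` are labelled evaluation groups under
    shifted confounder values (groups C1..Cn).
    """

    side: SideStudy
    main: FeatureTable
    test_groups: list[FeatureTable]
    oracle_extra: FeatureTable | None = None

    def __post_init__(self) -> None:
        names = self.side.feature_names
        members: list[FeatureTable] = [self.main, *self.test_groups]
        if self.oracle_extra is not None:
            members.append(self.oracle_extra)
        for t in members:
            if t.feature_names != names:
                raise ValueError("all bundle tables must share identical feature names")
        if self.main.labels is None or len(np.unique(self.main.labels)) != 2:
            raise ValueError("main study must carry both classes")
        for g, t in enumerate(self.test_groups):
            if t.labels is None or len(np.unique(t.labels)) != 2:
                raise ValueError(f"test group {g} must carry both classes")
        if self.oracle_extra is not None and self.oracle_extra.labels is None:
            raise ValueError("oracle_extra must be labelled")

    @property
    def feature_names(self) -> list[str]:
        return self.side.feature_names


def _parse_numeric(df: pd.DataFrame, path: str) -> np.ndarray:
    """Convert a feature frame to floats, naming the first bad cell."""
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: non-numeric feature cell at row {i}, column {col!r}"
            )
        if converted.isna().any():
            i = int(np.argmax(converted.isna().to_numpy()))
            raise ValueError(f"{path}: missing value at row {i}, column {col!r}")
        out[:, j] = converted.to_numpy(dtype=float)
    return out


def read_feature_table(
    path: str,
    label_column: str | None = None,
    confounder_column: str | None = None,
    delimiter: str = ",",
) -> FeatureTable:
    """Read a delimited feature table with a header row.

    ``label_column`` must hold exactly two distinct values; they are mapped to
    {0, 1} by lexicographic order of their string form (the mapping is
    logged).  Named metadata columns are excluded from the feature matrix.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=delimiter))
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate feature names {dupes}")

    df = pd.read_csv(path, sep=delimiter, dtype=object)
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"{path}: label column {label_column!r} not found")
        raw = df.pop(label_column)
        classes = sorted(raw.astype(str).unique())
        if len(classes) != 2:
            raise ValueError(
                f"{path}: label column {label_column!r} has {len(classes)} "
                "distinct values, expected exactly 2"
            )
        mapping = {classes[0]: 0, classes[1]: 1}
        logger.info("label mapping for %s: %s", path, mapping)
        labels = raw.astype(str).map(mapping).to_numpy()
    confounder = None
    if confounder_column is not None:
        if confounder_column not in df.columns:
            raise ValueError(f"{path}: confounder column {confounder_column!r} not found")
        confounder = df.pop(confounder_column).to_numpy()

    if df.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns")
    values = _parse_numeric(df, path)
    return FeatureTable(
        values=values,
        feature_names=list(df.columns),
        labels=labels,
        confounder=confounder,
    )


def write_feature_table(
    table: FeatureTable, path: str, delimiter: str = ","
) -> None:
    """Write a feature table as delimited text (header + one row per observation).

    Labels and confounder values, when present, are appended as trailing
    ``label`` / ``confounder`` columns.  Floats are written with 17
    significant digits so a read-back is value-identical.
    """
    df = pd.DataFrame(table.values, columns=table.feature_names)
    if table.labels is not None:
        df["label"] = table.labels
    if table.confounder is not None:
        df["confounder"] = table.confounder
    df.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FORMAT)


def read_side_study(
    path: str,
    confounder_column: str,
    subject_column: str | None = None,
    delimiter: str = ",",
) -> SideStudy:
    """Read a side study from one file holding both measurement groups.

    The confounder column must take exactly two distinct values; the lower
    one (lexicographically) becomes group ``a``.  When ``subject_column`` is
    given the study is paired: each subject must appear exactly once per
    confounder value and rows are matched by subject ID (unmatched subjects
    are an error).  Without a subject column the study is unpaired.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=object)
    if confounder_column not in df.columns:
        raise ValueError(f"{path}: confounder column {confounder_column!r} not found")
    conf = df.pop(confounder_column).astype(str).to_numpy()
    levels = sorted(set(conf))
    if len(levels) != 2:
        raise ValueError(
            f"{path}: confounder column must take exactly 2 values, got {levels}"
        )
    va, vb = levels

    subjects = None
    if subject_column is not None:
        if subject_column not in df.columns:
            raise ValueError(f"{path}: subject column {subject_column!r} not found")
        subjects = df.pop(subject_column).astype(str).to_numpy()
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns")
    table = FeatureTable(values=_parse_numeric(df, path), feature_names=list(df.columns))

    if subjects is None:
        a = table.subset_rows(np.flatnonzero(conf == va))
        b = table.subset_rows(np.flatnonzero(conf == vb))
        return SideStudy(mode="unpaired", a=a, b=b)

    idx_a = np.flatnonzero(conf == va)
    idx_b = np.flatnonzero(conf == vb)
    rows_a = {subjects[i]: i for i in idx_a}
    rows_b = {subjects[i]: i for i in idx_b}
    if len(rows_a) != len(idx_a) or len(rows_b) != len(idx_b):
        raise ValueError(f"{path}: a subject appears twice under one confounder value")
    unmatched = set(rows_a) ^ set(rows_b)
    if unmatched:
        raise ValueError(
            f"{path}: subjects without a measurement under both confounder "
            f"values: {sorted(unmatched)[:5]}"
        )
    order = sorted(rows_a)
    a = table.subset_rows(np.asarray([rows_a[s] for s in order]))
    b = table.subset_rows(np.asarray([rows_b[s] for s in order]))
    return SideStudy(mode="paired", a=a, b=b)
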