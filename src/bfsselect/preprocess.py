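"""Tabular data handling for binary-classification feature selection.

A :class:`FeatureTable` is the universal carrier throughout the package: an
``n x d`` numeric matrix (NaN marks a missing cell), a binary label vector and
feature names.  This module reads CSV data into that shape and provides the
standard cleaning pipeline: duplicate/missing-row removal, KNN or mean
imputation, z-score standardization and stratified train/validation splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureTable",
    "ScalerParams",
    "SplitPair",
    "read_table",
    "impute_knn",
    "impute_mean",
    "drop_missing",
    "standardize",
    "destandardize",
    "stratified_split",
]


@dataclass
class FeatureTable:
    """Numeric feature matrix with binary labels.

    Parameters
    ----------
    values : ndarray of shape (n, d)
        Feature matrix; missing cells are NaN.
    labels : ndarray of shape (n,)
        Class labels in {0, 1} (1 = positive / "normal").
    feature_names : list of str
        One name per column.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"row count {self.values.shape[0]}"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, got extra values {sorted(bad)}")
        self.labels = self.labels.astype(int)
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.labels.copy(), list(self.feature_names))

    def to_dataframe(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[label_column] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str) -> "FeatureTable":
        if label_column not in df.columns:
            raise KeyError(f"label column {label_column!r} not present in data")
        labels = _coerce_labels(df[label_column])
        feats = df.drop(columns=[label_column])
        values = feats.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        return cls(values, labels, list(feats.columns))


@dataclass
class ScalerParams:
    """Per-feature location/scale of a z-score transform.

    ``sigma`` is the population standard deviation of the training data
    (the scikit-learn scaler convention); constant features get sigma = 1
    so their z-scores are exactly 0.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D arrays of equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive (constant columns use 1)")


@dataclass
class SplitPair:
    """A stratified train/validation partition of one FeatureTable."""

    train: FeatureTable
    val: FeatureTable
    fraction: float
    seed: int
    train_idx: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    val_idx: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _coerce_labels(col: pd.Series) -> np.ndarray:
    """Map a label column onto {0, 1}.

    String labels are matched case-insensitively: "normal" -> 1,
    "abnormal" -> 0.  Numeric labels must already be 0/1.
    """
    if col.dtype == object or pd.api.types.is_string_dtype(col):
        mapping = {"normal": 1, "abnormal": 0, "1": 1, "0": 0}
        lowered = col.astype(str).str.strip().str.lower()
        unknown = sorted(set(lowered) - set(mapping))
        if unknown:
            raise ValueError(f"label values not mappable onto 0/1: {unknown}")
        return lowered.map(mapping).to_numpy(dtype=int)
    arr = col.to_numpy()
    bad = sorted(set(np.unique(arr)) - {0, 1})
    if bad:
        raise ValueError(f"label values not binary 0/1: {bad}")
    return arr.astype(int)


def read_table(path, label_column: str = "class") -> FeatureTable:
    """Read a CSV file into a :class:`FeatureTable`.

    All non-label columns become numeric features; cells that do not parse
    as numbers (including empty strings and "NaN") become missing cells.
    """
    df = pd.read_csv(path)
    return FeatureTable.from_dataframe(df, label_column)


def drop_missing(t: FeatureTable) -> FeatureTable:
    """Remove rows containing missing cells, then exact duplicate rows."""
    keep = ~np.isnan(t.values).any(axis=1)
    values, labels = t.values[keep], t.labels[keep]
    if values.shape[0] == 0:
        raise ValueError("dropping missing rows removed every sample")
    rows = pd.DataFrame(np.column_stack([values, labels]))
    dedup = ~rows.duplicated().to_numpy()
    return FeatureTable(values[dedup], labels[dedup], t.feature_names)


def impute_knn(t: FeatureTable, k: int = 10) -> FeatureTable:
    """Fill missing cells with the mean of the k nearest complete neighbours.

    Distances are Euclidean over mutually observed features, rescaled by
    sqrt(d / #shared); rows missing the target feature are ineligible
    donors.  If fewer than ``k`` donors exist for some feature, all
    eligible donors are used and a warning is emitted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = np.isnan(t.values)
    if not missing.any():
        return t.copy()
    if missing.all(axis=1).any():
        raise ValueError("a row has no observed features; cannot impute")
    all_missing = missing.all(axis=0)
    if all_missing.any():
        names = [t.feature_names[j] for j in np.where(all_missing)[0]]
        raise ValueError(f"feature(s) missing in every row: {names}")
    donor_counts = (~missing).sum(axis=0)
    short = donor_counts[missing.any(axis=0)].min()
    if short < k:
        warnings.warn(
            f"only {short} eligible neighbours for some feature; "
            f"using all of them instead of k={k}",
            stacklevel=2,
        )
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(t.values)
    return FeatureTable(filled, t.labels.copy(), t.feature_names)


def impute_mean(t: FeatureTable) -> FeatureTable:
    """Fill each missing cell with its feature's observed mean."""
    missing = np.isnan(t.values)
    if missing.all(axis=0).any():
        bad = [t.feature_names[j] for j in np.where(missing.all(axis=0))[0]]
        raise ValueError(f"feature(s) missing in every row: {bad}")
    col_means = np.nanmean(t.values, axis=0)
    filled = np.where(missing, col_means, t.values)
    return FeatureTable(filled, t.labels.copy(), t.feature_names)


def standardize(train: FeatureTable, *others: FeatureTable):
    """Z-score features using the training table's mean and population SD.

    Returns ``(params, train_z, *others_z)``.  Every extra table is
    transformed with the training parameters, never its own.
    """
    if train.n == 0:
        raise ValueError("training table is empty")
    for tab in (train, *others):
        if tab.has_missing:
            raise ValueError("missing cells present; impute or drop before standardizing")
    mu = train.values.mean(axis=0)
    sigma = train.values.std(axis=0)  # population SD (ddof=0)
    sigma = np.where(sigma == 0.0, 1.0, sigma)
    params = ScalerParams(mu, sigma)
    out = [
        FeatureTable((tab.values - mu) / sigma, tab.labels.copy(), tab.feature_names)
        for tab in (train, *others)
    ]
    return (params, *out)


def destandardize(params: ScalerParams, t: FeatureTable) -> FeatureTable:
    """Invert :func:`standardize` on a transformed table."""
    return FeatureTable(t.values * params.sigma + params.mu, t.labels.copy(), t.feature_names)


def stratified_split(t: FeatureTable, fraction: float = 0.8, seed: int = 0) -> SplitPair:
    """Split into train/validation parts preserving class proportions.

    ``fraction`` is the training share.  Deterministic under a fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    counts = np.bincount(t.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError(f"each class needs at least 2 samples, got counts {counts.tolist()}")
    idx = np.arange(t.n)
    train_idx, val_idx = train_test_split(
        idx, train_size=fraction, random_state=seed, stratify=t.labels
    )
    train_idx = np.sort(train_idx)
    val_idx = np.sort(val_idx)
    mk = lambda ix: FeatureTable(t.values[ix], t.labels[ix], t.feature_names)
    return SplitPair(mk(train_idx), mk(val_idx), fraction, seed, train_idx, val_idx)
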