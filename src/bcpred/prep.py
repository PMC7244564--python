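"""Labeled-dataset assembly and preprocessing.

The pipeline order mirrors the modelling workflow: stack the positive
(label 1, disease-related) and negative (label 0, non-cancer) feature
matrices, then ``clean`` (duplicate rows, NA rows, zero-variance columns),
min-max scale every feature into [0, 1], and balance the classes with SMOTE.

By default scaling, SMOTE and (downstream) feature selection are fitted on
the full dataset before cross-validation. That replicates the original
workflow but leaks information from the evaluation folds into the
preprocessing; the benchmark harness offers a leakage-safe mode that re-fits
all of it inside each training fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Feature matrix plus aligned binary labels (1 = positive class)."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have the same length")
        if not set(np.unique(self.labels)).issubset({0, 1}):
            raise ValueError("labels must be binary 0/1")
        self.labels = pd.Series(
            np.asarray(self.labels, dtype=int), index=self.features.index, name="label"
        )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def class_counts(self) -> Dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out["label"] = self.labels.to_numpy()
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path, index_col=0)
        if "label" not in df.columns:
            raise ValueError(f"{path}: no 'label' column")
        return cls(df.drop(columns="label"), df["label"])


def assemble(pos_matrix: pd.DataFrame, neg_matrix: pd.DataFrame) -> LabeledDataset:
    """Stack positive rows (label 1) over negative rows (label 0).

    Columns are aligned by name; a genuine column-set mismatch is an error.
    """
    if len(pos_matrix) == 0 or len(neg_matrix) == 0:
        raise ValueError("both classes must be non-empty")
    if set(pos_matrix.columns) != set(neg_matrix.columns):
        missing = set(pos_matrix.columns) ^ set(neg_matrix.columns)
        raise ValueError(f"column sets differ between classes: {sorted(missing)[:5]}...")
    neg_matrix = neg_matrix[pos_matrix.columns]  # align order by name
    features = pd.concat([pos_matrix, neg_matrix], axis=0)
    labels = pd.Series(
        [1] * len(pos_matrix) + [0] * len(neg_matrix), index=features.index, name="label"
    )
    return LabeledDataset(features, labels)


def clean(ds: LabeledDataset) -> Tuple[LabeledDataset, Dict[str, int]]:
    """Remove duplicate rows, NA rows, then zero-variance columns.

    Returns the cleaned dataset and a removal report
    ``{"duplicate_rows", "na_rows", "zero_variance_columns"}``. Idempotent.
    """
    X, y = ds.features, ds.labels
    dup = X.duplicated(keep="first")
    X, y = X.loc[~dup], y.loc[~dup.to_numpy()]
    na = X.isna().any(axis=1)
    X, y = X.loc[~na], y.loc[~na.to_numpy()]
    if len(X) == 0:
        raise ValueError("clean removed every row")
    zero_var = (X.max(axis=0) - X.min(axis=0)) == 0
    X = X.loc[:, ~zero_var]
    if X.shape[1] == 0:
        raise ValueError("clean removed every column")
    report = {
        "duplicate_rows": int(dup.sum()),
        "na_rows": int(na.sum()),
        "zero_variance_columns": int(zero_var.sum()),
    }
    if any(report.values()):
        logger.info("clean: %s", report)
    return LabeledDataset(X, y), report


@dataclass
class ScalerState:
    """Per-column min/max observed at fit time; maps features into [0, 1].

    Values seen at apply time outside the fitted range are clipped to [0, 1]
    so that downstream chi-squared selection keeps its non-negativity
    precondition on new (screening) data.
    """

    columns: list = field(default_factory=list)
    data_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    data_max: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "columns": list(self.columns),
                "data_min": self.data_min.tolist(),
                "data_max": self.data_max.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalerState":
        d = json.loads(text)
        return cls(d["columns"], np.asarray(d["data_min"]), np.asarray(d["data_max"]))


def fit_scaler(ds: LabeledDataset) -> ScalerState:
    """Record per-column min and max; constant columns are rejected."""
    X = ds.features
    mn = X.min(axis=0).to_numpy(dtype=float)
    mx = X.max(axis=0).to_numpy(dtype=float)
    constant = mn == mx
    if constant.any():
        bad = list(X.columns[constant][:5])
        raise ValueError(
            f"constant column(s) {bad} cannot be min-max scaled; run clean() first"
        )
    return ScalerState(list(X.columns), mn, mx)


def apply_scaler(state: ScalerState, matrix: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
    """Affine map (x - min) / (max - min) per column, clipped to [0, 1]."""
    missing = [c for c in state.columns if c not in matrix.columns]
    if missing:
        raise ValueError(f"columns absent at apply time: {missing[:5]}...")
    X = matrix[state.columns].to_numpy(dtype=float)
    scaled = (X - state.data_min) / (state.data_max - state.data_min)
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return pd.DataFrame(scaled, index=matrix.index, columns=state.columns)


def inverse_scaler(state: ScalerState, matrix: pd.DataFrame) -> pd.DataFrame:
    X = matrix[state.columns].to_numpy(dtype=float)
    return pd.DataFrame(
        X * (state.data_max - state.data_min) + state.data_min,
        index=matrix.index,
        columns=state.columns,
    )


def smote_balance(
    ds: LabeledDataset, k_neighbors: int = 5, seed: int = 0
) -> LabeledDataset:
    """Oversample the minority class with SMOTE until the classes are equal.

    Each synthetic point is x_i + u * (x_nn - x_i) with u ~ U(0, 1), where
    x_i is a minority point and x_nn one of its k minority-class nearest
    neighbours (Euclidean). Deterministic under ``seed``. An already-balanced
    dataset is returned unchanged.
    """
    counts = ds.class_counts
    if set(counts) != {0, 1}:
        raise ValueError("smote_balance needs both classes present")
    n0, n1 = counts[0], counts[1]
    if n0 == n1:
        return ds
    minority = 1 if n1 < n0 else 0
    n_needed = abs(n0 - n1)
    X_min = ds.features.loc[(ds.labels == minority).to_numpy()]
    if len(X_min) <= k_neighbors:
        raise ValueError(
            f"minority class has {len(X_min)} members; needs > k_neighbors={k_neighbors}"
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min.to_numpy())
    # first neighbour is the point itself
    neighbor_idx = nn.kneighbors(X_min.to_numpy(), return_distance=False)[:, 1:]
    base = rng.integers(0, len(X_min), size=n_needed)
    pick = rng.integers(0, k_neighbors, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    Xb = X_min.to_numpy()[base]
    Xn = X_min.to_numpy()[neighbor_idx[base, pick]]
    synth = Xb + u[:, None] * (Xn - Xb)
    synth_ids = [f"smote_{minority}_{i}" for i in range(n_needed)]
    synth_df = pd.DataFrame(
        synth, index=pd.Index(synth_ids, name=ds.features.index.name), columns=ds.features.columns
    )
    features = pd.concat([ds.features, synth_df], axis=0)
    labels = pd.concat(
        [ds.labels, pd.Series([minority] * n_needed, index=synth_df.index, name="label")]
    )
    return LabeledDataset(features, labels)
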