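"""Feature reduction: chi-squared univariate k-best selection, or PCA.

The chi-squared statistic for a non-negative feature x and binary labels is
the contingency form standard for univariate feature selection: observed
values are the per-class column sums O_c = sum of x over class c, expected
values E_c = (n_c / n) * sum(x), and the score is sum_c (O_c - E_c)^2 / E_c.
Ties in the score are broken by column order, making the top-k sets nested
in k.

PCA keeps the k leading orthonormal components of the column-centred data;
the sign of each component is fixed by forcing its largest-magnitude loading
positive, so results are reproducible across runs and BLAS builds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import chi2

from .prep import LabeledDataset

MODES = ("kbest-chi2", "pca", "none")


@dataclass
class SelectorState:
    """Fitted feature-reduction state, serializable to JSON."""

    mode: str
    k: int
    # kbest
    selected: Optional[List[str]] = None
    scores: Optional[np.ndarray] = None
    # pca
    input_columns: Optional[List[str]] = None
    mean: Optional[np.ndarray] = None
    components: Optional[np.ndarray] = None
    explained_variance_ratio: Optional[np.ndarray] = None

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return json.dumps(
            {
                "mode": self.mode,
                "k": self.k,
                "selected": self.selected,
                "scores": arr(self.scores),
                "input_columns": self.input_columns,
                "mean": arr(self.mean),
                "components": arr(self.components),
                "explained_variance_ratio": arr(self.explained_variance_ratio),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectorState":
        d = json.loads(text)

        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            mode=d["mode"],
            k=d["k"],
            selected=d["selected"],
            scores=arr(d["scores"]),
            input_columns=d["input_columns"],
            mean=arr(d["mean"]),
            components=arr(d["components"]),
            explained_variance_ratio=arr(d["explained_variance_ratio"]),
        )


def chi2_scores(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Per-column chi-squared score between non-negative features and labels."""
    Xv = X.to_numpy(dtype=float)
    if (Xv < 0).any():
        raise ValueError("chi-squared selection requires non-negative features")
    return chi2(Xv, np.asarray(y))[0]


def fit_kbest_chi2(ds: LabeledDataset, k: int) -> SelectorState:
    """Keep the k columns with the largest chi-squared score.

    Ties are broken by column order; the selected list is stored in score
    order (descending) but transform preserves original column order.
    """
    ncols = ds.features.shape[1]
    if not 1 <= k <= ncols:
        raise ValueError(f"k={k} must be in 1..{ncols}")
    scores = chi2_scores(ds.features, ds.labels.to_numpy())
    # stable: equal scores keep earlier columns first
    order = np.lexsort((np.arange(ncols), -np.nan_to_num(scores, nan=-np.inf)))
    top = order[:k]
    selected = [ds.features.columns[i] for i in top]
    return SelectorState(
        mode="kbest-chi2", k=k, selected=selected, scores=scores[top],
        input_columns=list(ds.features.columns),
    )


def fit_pca(ds: LabeledDataset, k: int, seed: int = 0) -> SelectorState:
    """Fit k principal components with a deterministic sign convention."""
    X = ds.features
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(rows, columns)={min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    pca.fit(X.to_numpy(dtype=float))
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return SelectorState(
        mode="pca",
        k=k,
        input_columns=list(X.columns),
        mean=pca.mean_,
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def fit_none(ds: LabeledDataset) -> SelectorState:
    """Identity selector (no reduction)."""
    return SelectorState(
        mode="none", k=ds.features.shape[1], input_columns=list(ds.features.columns)
    )


def fit_selector(ds: LabeledDataset, mode: str, k: int = 0, seed: int = 0) -> SelectorState:
    if mode == "kbest-chi2":
        return fit_kbest_chi2(ds, k)
    if mode == "pca":
        return fit_pca(ds, k, seed)
    if mode == "none":
        return fit_none(ds)
    raise ValueError(f"unknown selector mode {mode!r}; valid: {MODES}")


def transform(state: SelectorState, matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted selector to a matrix with matching columns."""
    if state.mode == "none":
        missing = [c for c in state.input_columns if c not in matrix.columns]
        if missing:
            raise ValueError(f"missing columns: {missing[:5]}...")
        return matrix[state.input_columns]
    if state.mode == "kbest-chi2":
        missing = [c for c in state.selected if c not in matrix.columns]
        if missing:
            raise ValueError(f"missing selected columns: {missing[:5]}...")
        keep = [c for c in matrix.columns if c in set(state.selected)]
        return matrix[keep]
    if state.mode == "pca":
        missing = [c for c in state.input_columns if c not in matrix.columns]
        if missing:
            raise ValueError(f"missing columns: {missing[:5]}...")
        X = matrix[state.input_columns].to_numpy(dtype=float)
        proj = (X - state.mean) @ state.components.T
        return pd.DataFrame(
            proj, index=matrix.index, columns=[f"PC{i+1}" for i in range(state.k)]
        )
    raise ValueError(f"unknown selector mode {state.mode!r}")
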