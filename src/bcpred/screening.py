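"""Screen external protein lists with a saved model and compare alteration burden.

``screen`` pushes FASTA records through a persisted :class:`ModelBundle`
(featurize with the bundle's families and descriptor config, min-max scale
with clipping, reduce, score) and ranks candidates by predicted
positive-class probability. ``compare_burden`` contrasts per-protein genomic
alteration counts between predicted-positive and predicted-negative groups
with a Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bench import ModelBundle
from .descriptors import featurize
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ["protein_id", "tag", "probability", "label"]


def screen(
    bundle: ModelBundle,
    records: Sequence[ProteinRecord],
    tag: str = "",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score records with a saved bundle, sorted by probability descending.

    Sequences shorter than the bundle's descriptor minimum length are
    dropped with a logged reason. Label 1 iff probability >= threshold.
    """
    min_len = bundle.config.min_length if {"APAAC", "MB"} & set(bundle.families) else 3
    usable = []
    for rec in records:
        if len(rec) < min_len:
            logger.warning(
                "screen: dropping %r (length %d < minimum %d for families %s)",
                rec.id, len(rec), min_len, list(bundle.families),
            )
            continue
        usable.append(rec)
    if not usable:
        raise ValueError("no records long enough to screen")
    matrix = featurize(usable, bundle.families, bundle.config)
    proba = bundle.predict_proba(matrix)
    out = pd.DataFrame(
        {
            "protein_id": matrix.index.to_numpy(),
            "tag": tag,
            "probability": proba,
            "label": (proba >= threshold).astype(int),
        },
        columns=PREDICTION_COLUMNS,
    )
    # stable sort: ties keep input order, making reruns byte-identical
    out = out.sort_values("probability", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration (handles ties).

    Enumerates every split of the pooled values into groups of sizes
    (n1, n2); p is the probability of a U at least as far from n1*n2/2 as
    the observed one. Only used when both groups have <= 8 members.
    """
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    dev = abs(u_obs - center)
    total = comb(n1 + n2, n1)
    hits = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def compare_burden(
    burden: pd.DataFrame,
    predictions: pd.DataFrame,
    count_column: str = "total",
) -> dict:
    """Mann-Whitney U on alteration counts: predicted 1 vs predicted 0.

    ``burden`` has a ``protein_id`` column (or index) and a non-negative
    count column; ``predictions`` is the output of :func:`screen`. Uses
    exact enumeration when both groups have at most 8 members, otherwise
    the tie-corrected normal approximation. Returns the U statistic of the
    predicted-positive group, the two-sided p, group means and sizes.
    """
    if "protein_id" in burden.columns:
        burden = burden.set_index("protein_id")
    if (burden[count_column] < 0).any():
        raise ValueError("alteration counts must be non-negative")
    merged = predictions.merge(
        burden[[count_column]], left_on="protein_id", right_index=True, how="inner"
    )
    g1 = merged.loc[merged["label"] == 1, count_column].to_numpy(dtype=float)
    g0 = merged.loc[merged["label"] == 0, count_column].to_numpy(dtype=float)
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both predicted groups must be non-empty")
    if len(g1) <= 8 and len(g0) <= 8:
        u, p = _exact_mannwhitney(g1, g0)
        method = "exact-enumeration"
    else:
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "normal-approximation"
    return {
        "U": u,
        "p_value": p,
        "method": method,
        "mean_predicted_1": float(g1.mean()),
        "mean_predicted_0": float(g0.mean()),
        "n_predicted_1": int(len(g1)),
        "n_predicted_0": int(len(g0)),
    }
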