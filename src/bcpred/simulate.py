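"""Synthetic two-class protein corpora and toy alteration-burden tables.

The generator emulates the study design of a two-class sequence-composition
problem: negative sequences are drawn i.i.d. from a baseline residue
distribution (uniform 1/20 by default, for analytic transparency); positive
sequences come from the mixture ``(1 - delta) * baseline + delta *
Uniform(S)`` where S is a small designated residue subset (default K, R —
a crude compositional charge bias). ``delta`` therefore moves probability
mass delta onto S, so even 20-feature composition models can detect the
signal, while k-mer families inherit it. ``delta = 0`` makes the classes
exchangeable.

``generate_burden`` emulates a per-protein genomic-alteration count table:
Poisson counts whose mean is shifted by ``effect`` for predicted-positive
proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, ProteinRecord

#: baseline per-protein alteration count in a tumour cohort (order of
#: magnitude of the non-cancer group means reported for such cohorts).
DEFAULT_BURDEN_MEAN = 85.0


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic corpus.

    Defaults mirror the modelled dataset: 140 positives vs 233 negatives,
    lengths 50-500 (>= 31 so every descriptor family is computable), and a
    compositional shift delta = 0.05 onto the subset ``shift_residues``.
    """

    n_pos: int = 140
    n_neg: int = 233
    min_length: int = 50
    max_length: int = 500
    delta: float = 0.05
    shift_residues: Tuple[str, ...] = ("K", "R")
    seed: int = 0
    baseline: Tuple[float, ...] = field(default_factory=lambda: tuple([0.05] * 20))

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")
        if self.min_length < 31:
            raise ValueError("min_length must be >= 31 so APAAC/MB are computable")
        if self.max_length < self.min_length:
            raise ValueError("max_length < min_length")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        bad = set(self.shift_residues) - set(ALPHABET)
        if bad:
            raise ValueError(f"unknown residues in shift subset: {sorted(bad)}")
        p = np.asarray(self.baseline, dtype=float)
        if p.shape != (20,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("baseline must be a 20-point probability vector")


def class_distributions(config: FixtureConfig) -> Tuple[np.ndarray, np.ndarray]:
    """(negative, positive) residue distributions implied by the config."""
    base = np.asarray(config.baseline, dtype=float)
    shift = np.zeros(20)
    for aa in config.shift_residues:
        shift[ALPHABET.index(aa)] = 1.0 / len(config.shift_residues)
    pos = (1.0 - config.delta) * base + config.delta * shift
    return base, pos


def _draw(rng, n, prefix, p, lmin, lmax) -> List[ProteinRecord]:
    records = []
    for i in range(n):
        length = int(rng.integers(lmin, lmax + 1))
        idx = rng.choice(20, size=length, p=p)
        seq = "".join(ALPHABET[j] for j in idx)
        records.append(ProteinRecord(f"{prefix}_{i + 1:04d}", seq))
    return records


def generate_corpus(
    config: FixtureConfig,
) -> Tuple[List[ProteinRecord], List[ProteinRecord]]:
    """Draw (positive, negative) record lists; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    base, pos_p = class_distributions(config)
    positives = _draw(rng, config.n_pos, "POS", pos_p, config.min_length, config.max_length)
    negatives = _draw(rng, config.n_neg, "NEG", base, config.min_length, config.max_length)
    return positives, negatives


def generate_burden(
    predictions: pd.DataFrame,
    effect: float = 0.0,
    seed: int = 0,
    base_mean: float = DEFAULT_BURDEN_MEAN,
) -> pd.DataFrame:
    """Poisson alteration counts, mean shifted by ``effect`` for label-1 rows.

    Returns a table with columns protein_id, cna, mutation, mrna, protein,
    total; the four typed counts split the total mean evenly.
    """
    if len(predictions) == 0:
        raise ValueError("predictions must be non-empty")
    rng = np.random.default_rng(seed)
    labels = predictions["label"].to_numpy()
    means = base_mean + effect * labels
    parts = {}
    for name in ("cna", "mutation", "mrna", "protein"):
        parts[name] = rng.poisson(means / 4.0)
    table = pd.DataFrame(
        {"protein_id": predictions["protein_id"].to_numpy(), **parts}
    )
    table["total"] = table[["cna", "mutation", "mrna", "protein"]].sum(axis=1)
    return table
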