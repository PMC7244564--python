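"""Protein sequence descriptor families and their concatenation (Mix).

Five families are computed from the primary sequence alone:

AC
    amino-acid composition — the 20 residue fractions.
DC
    di-amino-acid composition — fractions of the 400 overlapping dipeptides.
TC
    tri-amino-acid composition — fractions of the 8000 overlapping tripeptides.
APAAC
    amphiphilic pseudo-amino-acid composition — the 20 residue fractions
    extended with 2*lambda sequence-order correlation factors built from
    standardized hydrophobicity (H1) and hydrophilicity (H2) scales and
    jointly normalized with weight w. With the default lambda = 30 this is
    80 features.
MB
    normalized Moreau-Broto autocorrelation — for each of 8 standardized
    physicochemical scales, the lag-d average of products of the scale value
    along the sequence, d = 1..nlag (default 30), i.e. 240 features.

``Mix`` is the concatenation of all five families in the fixed order
AC, DC, TC, APAAC, MB (8740 columns). Feature names are canonical and
stable: single letters for AC, two/three-letter strings for DC/TC,
``Pc1.A``..``Pc1.Y`` and ``Pc2.1``..``Pc2.2λ`` for APAAC, and
``<scale>.lag<d>`` for MB.

Scale standardization (shared with the test oracles): each 20-value scale is
centred to zero mean and divided by its sample standard deviation (ddof=1)
over the 20 alphabet values.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, ProteinRecord

FAMILIES = ("AC", "DC", "TC", "APAAC", "MB")

_AA_INDEX: Dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

AC_NAMES: List[str] = list(ALPHABET)
DC_NAMES: List[str] = ["".join(p) for p in itertools.product(ALPHABET, repeat=2)]
TC_NAMES: List[str] = ["".join(p) for p in itertools.product(ALPHABET, repeat=3)]


class SequenceTooShortError(ValueError):
    """Sequence shorter than a descriptor family's minimum length."""


def _load_scales(filename: str) -> Dict[str, np.ndarray]:
    """Load a scale CSV shipped with the package: rows scales, columns A..Y."""
    with resources.files("bcpred.data").joinpath(filename).open() as fh:
        df = pd.read_csv(fh, comment="#", index_col=0)
    assert list(df.columns) == list(ALPHABET), f"{filename}: unexpected column order"
    return {name: row.to_numpy(dtype=float) for name, row in df.iterrows()}


def standardize_scale(values: np.ndarray) -> np.ndarray:
    """Zero-mean / unit sample-SD (ddof=1) standardization over the 20 values."""
    values = np.asarray(values, dtype=float)
    if values.shape != (20,):
        raise ValueError("a scale must have exactly 20 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) scale")
    return (values - values.mean()) / sd


@dataclass(frozen=True)
class DescriptorConfig:
    """Parameters of the APAAC and Moreau-Broto families.

    apaac_lambda
        number of sequence-order correlation tiers (λ); APAAC emits 20 + 2λ
        features.
    apaac_weight
        weight w of the sequence-order part in the joint normalization.
    mb_nlag
        maximum autocorrelation lag d; MB emits |scales| × nlag features.
    mb_scales / apaac_scales
        named 20-value physicochemical scales; defaults ship with the package.
    """

    apaac_lambda: int = 30
    apaac_weight: float = 0.05
    mb_nlag: int = 30
    mb_scales: Mapping[str, np.ndarray] = field(
        default_factory=lambda: _load_scales("mb_scales.csv")
    )
    apaac_scales: Mapping[str, np.ndarray] = field(
        default_factory=lambda: _load_scales("apaac_scales.csv")
    )

    def __post_init__(self) -> None:
        if self.apaac_lambda < 1 or self.mb_nlag < 1:
            raise ValueError("apaac_lambda and mb_nlag must be positive")
        if self.apaac_weight <= 0:
            raise ValueError("apaac_weight must be positive")
        if len(self.apaac_scales) != 2:
            raise ValueError("APAAC needs exactly two scales (H1, H2)")
        for name, vals in {**self.mb_scales, **self.apaac_scales}.items():
            if np.asarray(vals).shape != (20,):
                raise ValueError(f"scale {name!r} must have 20 values")

    @property
    def min_length(self) -> int:
        """Minimum sequence length when APAAC or MB is requested."""
        return max(self.apaac_lambda, self.mb_nlag) + 1

    def apaac_names(self) -> List[str]:
        return [f"Pc1.{aa}" for aa in ALPHABET] + [
            f"Pc2.{j}" for j in range(1, 2 * self.apaac_lambda + 1)
        ]

    def mb_names(self) -> List[str]:
        return [
            f"{scale}.lag{d}"
            for scale in self.mb_scales
            for d in range(1, self.mb_nlag + 1)
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "apaac_lambda": self.apaac_lambda,
                "apaac_weight": self.apaac_weight,
                "mb_nlag": self.mb_nlag,
                "mb_scales": {k: list(v) for k, v in self.mb_scales.items()},
                "apaac_scales": {k: list(v) for k, v in self.apaac_scales.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DescriptorConfig":
        d = json.loads(text)
        return cls(
            apaac_lambda=d["apaac_lambda"],
            apaac_weight=d["apaac_weight"],
            mb_nlag=d["mb_nlag"],
            mb_scales={k: np.asarray(v, float) for k, v in d["mb_scales"].items()},
            apaac_scales={k: np.asarray(v, float) for k, v in d["apaac_scales"].items()},
        )


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in sequence), dtype=np.int64, count=len(sequence))
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in sequence") from exc


def compute_ac(sequence: str) -> np.ndarray:
    """20 residue fractions, canonical alphabetical order; sums to 1."""
    if len(sequence) < 1:
        raise SequenceTooShortError("AC requires length >= 1")
    idx = _encode(sequence)
    return np.bincount(idx, minlength=20) / len(sequence)


def compute_dc(sequence: str) -> np.ndarray:
    """400 overlapping-dipeptide fractions (denominator N-1); sums to 1."""
    if len(sequence) < 2:
        raise SequenceTooShortError("DC requires length >= 2")
    idx = _encode(sequence)
    pair = 20 * idx[:-1] + idx[1:]
    return np.bincount(pair, minlength=400) / (len(sequence) - 1)


def compute_tc(sequence: str) -> np.ndarray:
    """8000 overlapping-tripeptide fractions (denominator N-2); sums to 1."""
    if len(sequence) < 3:
        raise SequenceTooShortError("TC requires length >= 3")
    idx = _encode(sequence)
    triple = 400 * idx[:-2] + 20 * idx[1:-1] + idx[2:]
    return np.bincount(triple, minlength=8000) / (len(sequence) - 2)


def compute_apaac(sequence: str, config: DescriptorConfig | None = None) -> np.ndarray:
    """Amphiphilic pseudo-amino-acid composition, (20 + 2λ)-vector summing to 1.

    Sequence-order factors interleave the two scales:
    τ_{2j-1} = mean_i H1'(s_i) H1'(s_{i+j}) and τ_{2j} likewise with H2',
    j = 1..λ, where H' is the standardized scale. With f the AC fractions and
    w the weight, the first 20 components are f_u / (1 + w Στ) and the last
    2λ are w τ_j / (1 + w Στ).
    """
    config = config or DescriptorConfig()
    lam, w = config.apaac_lambda, config.apaac_weight
    n = len(sequence)
    if n <= lam:
        raise SequenceTooShortError(
            f"APAAC with lambda={lam} requires length > {lam}, got {n}"
        )
    idx = _encode(sequence)
    h1_name, h2_name = list(config.apaac_scales)
    h1 = standardize_scale(config.apaac_scales[h1_name])[idx]
    h2 = standardize_scale(config.apaac_scales[h2_name])[idx]
    tau = np.empty(2 * lam)
    for j in range(1, lam + 1):
        tau[2 * j - 2] = np.dot(h1[:-j], h1[j:]) / (n - j)
        tau[2 * j - 1] = np.dot(h2[:-j], h2[j:]) / (n - j)
    denom = 1.0 + w * tau.sum()
    if denom <= 0:
        raise ValueError(f"APAAC normalization denominator {denom} <= 0")
    f = compute_ac(sequence)
    return np.concatenate([f / denom, w * tau / denom])


def compute_mb(sequence: str, config: DescriptorConfig | None = None) -> np.ndarray:
    """Normalized Moreau-Broto autocorrelation, one value per (scale, lag).

    AC_P(d) = (1/(N-d)) Σ_i P'(s_i) P'(s_{i+d}) with P' the standardized
    scale, d = 1..nlag; scales vary slowest, lags fastest.
    """
    config = config or DescriptorConfig()
    nlag = config.mb_nlag
    n = len(sequence)
    if n <= nlag:
        raise SequenceTooShortError(f"MB with nlag={nlag} requires length > {nlag}, got {n}")
    idx = _encode(sequence)
    out = np.empty(len(config.mb_scales) * nlag)
    pos = 0
    for vals in config.mb_scales.values():
        p = standardize_scale(vals)[idx]
        for d in range(1, nlag + 1):
            out[pos] = np.dot(p[:-d], p[d:]) / (n - d)
            pos += 1
    return out


_COMPUTE = {
    "AC": lambda s, c: compute_ac(s),
    "DC": lambda s, c: compute_dc(s),
    "TC": lambda s, c: compute_tc(s),
    "APAAC": compute_apaac,
    "MB": compute_mb,
}


def family_names(family: str, config: DescriptorConfig) -> List[str]:
    if family == "AC":
        return AC_NAMES
    if family == "DC":
        return DC_NAMES
    if family == "TC":
        return TC_NAMES
    if family == "APAAC":
        return config.apaac_names()
    if family == "MB":
        return config.mb_names()
    raise ValueError(f"unknown family {family!r}; valid: {FAMILIES}")


def normalize_families(families: Iterable[str]) -> Tuple[str, ...]:
    """Validate a family subset and return it in the fixed canonical order."""
    req = {f.upper() for f in families}
    if req == {"MIX"}:
        req = set(FAMILIES)
    unknown = req - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families {sorted(unknown)}; valid: {FAMILIES} or 'Mix'")
    if not req:
        raise ValueError("at least one descriptor family is required")
    return tuple(f for f in FAMILIES if f in req)


def featurize(
    records: Sequence[ProteinRecord],
    families: Iterable[str] = FAMILIES,
    config: DescriptorConfig | None = None,
    on_short: str = "strict",
) -> pd.DataFrame:
    """Compute the requested families for every record, concatenated by column.

    Returns a DataFrame indexed by protein id ("protein_id") with the
    families' columns concatenated in the fixed order AC, DC, TC, APAAC, MB.
    ``on_short='strict'`` raises on a sequence violating a family's minimum
    length; ``'drop'`` removes the record (logged).
    """
    import logging

    logger = logging.getLogger(__name__)
    config = config or DescriptorConfig()
    fams = normalize_families(families)
    if on_short not in ("strict", "drop"):
        raise ValueError("on_short must be 'strict' or 'drop'")
    columns = [name for fam in fams for name in family_names(fam, config)]
    rows: List[np.ndarray] = []
    ids: List[str] = []
    for rec in records:
        try:
            vec = np.concatenate([_COMPUTE[f](rec.sequence, config) for f in fams])
        except SequenceTooShortError as exc:
            if on_short == "strict":
                raise SequenceTooShortError(f"record {rec.id!r}: {exc}") from exc
            logger.warning("featurize: dropping record %r (%s)", rec.id, exc)
            continue
        ids.append(rec.id)
        rows.append(vec)
    if not rows:
        raise ValueError("no records survived featurization")
    mat = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="protein_id"), columns=columns)
    return mat
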