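"""Reading, validating, deduplicating and writing protein sequences in FASTA.

The unit of all I/O is :class:`ProteinRecord`: an identifier (the first
whitespace-delimited token of the FASTA header) plus a sequence over the
20-letter amino-acid alphabet. Sequences are upper-cased before validation.
Non-standard residues (B, J, O, U, X, Z, gaps, ...) are handled by an explicit
policy; the default ``strict`` fails loudly because silently mutating a
sequence corrupts every downstream descriptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Literal, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet, alphabetical one-letter codes.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

Policy = Literal["strict", "drop", "strip"]


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class InvalidResidueError(ValueError):
    """A sequence contains residues outside the 20-letter alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence keyed by its FASTA identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"ProteinRecord {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise InvalidResidueError(
                f"ProteinRecord {self.id!r}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _apply_policy(rec_id: str, seq: str, policy: Policy) -> str | None:
    """Return a cleaned sequence, or None if the record is to be dropped."""
    seq = seq.upper()
    bad = set(seq) - _ALPHABET_SET
    if not bad:
        return seq
    if policy == "strict":
        raise InvalidResidueError(
            f"record {rec_id!r} contains non-standard residues {sorted(bad)} "
            f"(policy=strict)"
        )
    if policy == "drop":
        logger.warning("dropping record %r: non-standard residues %s", rec_id, sorted(bad))
        return None
    if policy == "strip":
        logger.warning("stripping residues %s from record %r", sorted(bad), rec_id)
        stripped = "".join(c for c in seq if c in _ALPHABET_SET)
        return stripped or None
    raise ValueError(f"unknown policy {policy!r}")


def read_fasta(path: str | Path, policy: Policy = "strict") -> List[ProteinRecord]:
    """Parse a FASTA file into an ordered list of validated ProteinRecords.

    Parameters
    ----------
    path
        FASTA file (multi-line sequences allowed).
    policy
        ``strict``: raise on any non-standard residue; ``drop``: remove and
        log the offending record; ``strip``: delete the offending residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython is permissive
        raise FastaError(f"{path}: cannot parse as FASTA: {exc}") from exc
    if not raw:
        raise FastaError(f"{path}: no FASTA records found")
    records: List[ProteinRecord] = []
    for rec in raw:
        rec_id = rec.id.split()[0] if rec.id else ""
        if not rec_id:
            raise FastaError(f"{path}: record with empty header")
        seq = _apply_policy(rec_id, str(rec.seq), policy)
        if seq is None:
            continue
        records.append(ProteinRecord(rec_id, seq))
    return records


def deduplicate(
    records: Sequence[ProteinRecord], key: Literal["id", "sequence"] = "sequence"
) -> Tuple[List[ProteinRecord], int]:
    """Remove duplicate records, keeping the first occurrence.

    Returns the deduplicated list and the number of removals.
    """
    seen: set = set()
    kept: List[ProteinRecord] = []
    for rec in records:
        k = rec.id if key == "id" else rec.sequence
        if k in seen:
            continue
        seen.add(k)
        kept.append(rec)
    n_removed = len(records) - len(kept)
    if n_removed:
        logger.info("deduplicate(key=%s): removed %d of %d records", key, n_removed, len(records))
    return kept, n_removed


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 80) -> Path:
    """Write records to FASTA, wrapping sequence lines at `width` columns."""
    path = Path(path)
    records = list(records)
    if not records:
        logger.warning("write_fasta: writing an empty FASTA to %s", path)
    seqio_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqio_records)
    return path
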