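"""Protein sequence records and FASTA I/O.

Sequences are plain amino-acid strings over the 20 canonical residues plus
'X' for unresolved positions.  Anything else read from a FASTA file is mapped
to 'X' with a warning, so downstream alignment never sees an unknown symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with a unique whitespace-free identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"record id must be non-empty, no whitespace: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-canonical residues {sorted(bad)}; "
                "use sanitize_sequence() on read"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def sanitize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase and map residues outside the canonical alphabet to 'X'."""
    seq = seq.upper()
    if set(seq) <= ALPHABET:
        return seq
    cleaned = "".join(ch if ch in ALPHABET else "X" for ch in seq)
    logger.warning("record %s: non-canonical residues replaced by 'X'", record_id)
    return cleaned


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file; the first whitespace token is the id."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=sanitize_sequence(str(rec.seq), rec.id),
                description=rec.description[len(rec.id):].strip(),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns (byte-reproducible)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        SeqIO.write(seq_records, handle, "fasta")
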