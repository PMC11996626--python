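"""Annotated reference panel of PQQ-dependent dehydrogenases.

Each reference carries a clade label (XoxF5, GDH 1a, ...), the 1-based
position of the first aspartate of the metal-cofactor motif, and the clade's
canonical cofactor class.  Lanthanide-coordinating references carry D-x-D at
the motif; calcium-coordinating ones carry D-x-{A,T,S}.  The panel is the
anchor for both homology screening and motif projection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import ProteinRecord, read_fasta, write_fasta

CANONICAL_CLASSES = ("lanthanide", "calcium", "unknown")
CALCIUM_THIRD_RESIDUES = frozenset("ATS")


@dataclass(frozen=True)
class PanelEntry:
    id: str
    sequence: str
    clade: str
    motif_start: int  # 1-based index of the first motif aspartate
    canonical_class: str
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.canonical_class not in CANONICAL_CLASSES:
            raise ValueError(
                f"{self.id}: canonical_class {self.canonical_class!r} not in "
                f"{CANONICAL_CLASSES}"
            )
        if not (1 <= self.motif_start <= len(self.sequence) - 2):
            raise ValueError(
                f"{self.id}: motif_start {self.motif_start} outside "
                f"[1, {len(self.sequence) - 2}]"
            )
        if self.canonical_class in ("lanthanide", "calcium"):
            first = self.sequence[self.motif_start - 1]
            if first != "D":
                raise ValueError(
                    f"{self.id}: residue at motif_start is {first!r}, expected 'D' "
                    f"for a {self.canonical_class} reference"
                )

    @property
    def motif_triplet(self) -> str:
        i = self.motif_start - 1
        return self.sequence[i : i + 3]

    @property
    def record(self) -> ProteinRecord:
        return ProteinRecord(id=self.id, sequence=self.sequence)


@dataclass
class ReferencePanel:
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reference ids in panel")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, ref_id: str) -> PanelEntry:
        for e in self.entries:
            if e.id == ref_id:
                return e
        raise KeyError(ref_id)

    @property
    def records(self) -> list[ProteinRecord]:
        return [e.record for e in self.entries]

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.clade)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref_id": [e.id for e in self.entries],
                "clade": [e.clade for e in self.entries],
                "motif_start_1based": [e.motif_start for e in self.entries],
                "canonical_class": [e.canonical_class for e in self.entries],
                "confirmed": [e.confirmed for e in self.entries],
            }
        )

    def write(self, fasta_path: str | Path, tsv_path: str | Path) -> None:
        write_fasta(self.records, fasta_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | Path, tsv_path: str | Path) -> "ReferencePanel":
        seqs = {r.id: r.sequence for r in read_fasta(fasta_path)}
        entries: list[PanelEntry] = []
        with open(tsv_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                rid = row["ref_id"]
                if rid not in seqs:
                    raise ValueError(f"panel sidecar lists {rid!r} absent from FASTA")
                entries.append(
                    PanelEntry(
                        id=rid,
                        sequence=seqs[rid],
                        clade=row["clade"],
                        motif_start=int(row["motif_start_1based"]),
                        canonical_class=row["canonical_class"],
                        confirmed=str(row.get("confirmed", "False")).lower()
                        in ("true", "1", "yes"),
                    )
                )
        missing = set(seqs) - {e.id for e in entries}
        if missing:
            raise ValueError(f"FASTA references missing from sidecar: {sorted(missing)}")
        return cls(entries)
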