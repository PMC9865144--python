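"""Protein sequence containers and FASTA I/O.

Sequences are stored as uppercase one-letter codes restricted to the 20
standard amino acids plus ``X`` (unknown).  Biological residue numbers are
derived from string positions through an explicit ``numbering_offset``, so a
fragment excised from a larger protein (e.g. an SH3 domain or a proline-rich
region) keeps its native numbering:  ``biological number = 1-based index +
numbering_offset``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
VALID_CHARS = STANDARD_AA | {"X"}

_OFFSET_RE = re.compile(r"\boffset=(-?\d+)\b")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside the allowed set."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with an explicit biological-numbering offset.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        One-letter amino-acid codes; normalized to uppercase.  The 20
        standard codes plus ``X`` are accepted.
    numbering_offset : int
        Added to the 1-based string index to obtain biological residue
        numbers (default 0).
    """

    id: str
    residues: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        normalized = self.residues.upper()
        for pos, ch in enumerate(normalized, start=1):
            if ch not in VALID_CHARS:
                raise InvalidSequenceError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)

    def biological_number(self, index: int) -> int:
        """Biological residue number for a 1-based string index."""
        if not 1 <= index <= len(self.residues):
            raise IndexError(f"index {index} outside sequence of length {len(self)}")
        return index + self.numbering_offset


def parse_offset(description: str) -> int:
    """Extract an ``offset=<int>`` key from a FASTA description line (default 0)."""
    m = _OFFSET_RE.search(description)
    return int(m.group(1)) if m else 0


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file into :class:`ProteinSequence` objects.

    The record id (up to the first whitespace) becomes the protein id; an
    optional ``offset=<int>`` key anywhere in the description sets the
    numbering offset.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinSequence(
                id=rec.id,
                residues=str(rec.seq),
                numbering_offset=parse_offset(rec.description),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences to FASTA, encoding non-zero offsets on the header line."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.numbering_offset:
                header += f" offset={rec.numbering_offset}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def as_protein_sequence(obj: "ProteinSequence | str", id: str = "seq") -> ProteinSequence:
    if isinstance(obj, ProteinSequence):
        return obj
    return ProteinSequence(id=id, residues=obj)
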