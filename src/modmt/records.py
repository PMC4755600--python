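"""Protein records and FASTA I/O.

A :class:`ProteinRecord` is the unit every sequence-level operation
consumes: an identifier, an uppercase 20-letter amino-acid sequence and a
provenance tag saying whether the sequence was printed in a publication,
fetched from a database accession, or synthesized by the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidSequenceError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

Source = Literal["in_paper", "accession", "synthetic"]


def validate_protein_sequence(sequence: str) -> str:
    """Uppercase and validate a protein sequence.

    Raises
    ------
    InvalidSequenceError
        If the sequence is empty or contains a letter outside the 20
        canonical residues; the error names the character and its
        1-based position.
    """
    seq = sequence.upper()
    if not seq:
        raise InvalidSequenceError("protein sequence is empty")
    for i, ch in enumerate(seq, start=1):
        if ch not in _AA_SET:
            raise InvalidSequenceError(
                f"non-canonical residue {ch!r} at position {i}", char=ch, position=i
            )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with provenance."""

    id: str
    sequence: str
    source: Source = "synthetic"
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_protein_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, source: Source = "accession") -> list[ProteinRecord]:
    """Read protein records from a single- or multi-record FASTA file."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq), source=source,
                      description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InvalidSequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records to FASTA."""
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        for rec in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
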