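"""Viral sequence container and FASTA I/O.

Sequences are (+)-strand cDNA of dsRNA genomes, stored as uppercase DNA
(``U`` normalised to ``T`` on input). RNA-flavoured output (folding, loop
strings) converts back to ``U`` at the presentation layer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed or out-of-alphabet sequence input."""


@dataclass(frozen=True)
class ViralSequence:
    """A (+)-strand cDNA sequence of a viral dsRNA genome."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceError(f"{self.id}: non-DNA characters {sorted(bad)}")
        n_frac = self.residues.count("N") / len(self.residues)
        if n_frac >= 0.10:
            raise SequenceError(
                f"{self.id}: N fraction {n_frac:.2f} exceeds the 10% limit"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase, map RNA U to DNA T."""
    return raw.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path | io.TextIOBase) -> list[ViralSequence]:
    """Read a multi-record FASTA file into :class:`ViralSequence` objects.

    Records are normalised (uppercase, U -> T); ids and descriptions are
    preserved. An empty file yields an empty list.
    """
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    out = []
    try:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            residues = normalize_residues(str(rec.seq))
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            try:
                out.append(ViralSequence(id=rec.id, residues=residues, description=desc))
            except SequenceError as exc:
                raise SequenceError(f"parse error in record {i + 1}: {exc}") from exc
    finally:
        if handle is not path:
            handle.close()
    return out


def write_fasta(records: list[ViralSequence], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)
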