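"""Partition of a sequenced genome into 5'-extra / canonical / 3'-extra zones.

HTS-derived LA-virus cDNAs often run past the classical genome termini. The
canonical zone is anchored at the conserved 5' motif (``GAAAAA`` in ScV-LA
viruses, ``AATTAA`` in TdV-LAbarr1) and ends at the 3' terminus of the
conserved 3' motif (``CCATATGC``-style). Nucleotides outside it are the
"extra" sequences.

Coordinate convention (presentation layer): canonical bases are numbered
1..N from the 5' anchor; extra bases upstream are (-)1, (-)2, ... counting
away from the canonical start; extra bases downstream are (+)1, (+)2, ...
Internally everything is 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

from .sequences import ViralSequence


class PartitionError(ValueError):
    pass


class UnanchorableError(PartitionError):
    """Neither anchor motif nor reference can place the canonical zone."""


class AmbiguousAnchorError(PartitionError):
    """Several equally plausible anchor occurrences and no reference."""


class CoordinateError(ValueError):
    """Coordinate out of bounds for a partition."""


class Zone(Enum):
    FIVE_EXTRA = "FIVE_EXTRA"
    CANONICAL = "CANONICAL"
    THREE_EXTRA = "THREE_EXTRA"


@dataclass(frozen=True)
class PaperCoordinate:
    """Zone-qualified signed coordinate: (-)k / k / (+)k."""

    zone: Zone
    index: int

    def __str__(self) -> str:
        if self.zone is Zone.FIVE_EXTRA:
            return f"(-){abs(self.index)}"
        if self.zone is Zone.THREE_EXTRA:
            return f"(+){self.index}"
        return str(self.index)


@dataclass(frozen=True)
class GenomePartition:
    sequence: ViralSequence
    five_extra_len: int
    canonical_len: int
    three_extra_len: int
    anchor_5: str = ""
    anchor_3: str = ""
    anchor_method: str = "motif"

    def __post_init__(self) -> None:
        if self.canonical_len < 1 or min(self.five_extra_len, self.three_extra_len) < 0:
            raise PartitionError("zone lengths must be >= 0 with canonical >= 1")
        total = self.five_extra_len + self.canonical_len + self.three_extra_len
        if total != self.sequence.length:
            raise PartitionError(
                f"zone lengths {total} do not sum to sequence length {self.sequence.length}"
            )
        if self.anchor_method == "motif" and self.anchor_5:
            if not self.canonical_seq.startswith(self.anchor_5):
                raise PartitionError("canonical zone does not start with anchor_5")

    # -- zone sequences (internal 0-based half-open slices) --
    @property
    def five_extra_seq(self) -> str:
        return self.sequence.residues[: self.five_extra_len]

    @property
    def canonical_seq(self) -> str:
        a = self.five_extra_len
        return self.sequence.residues[a: a + self.canonical_len]

    @property
    def three_extra_seq(self) -> str:
        return self.sequence.residues[self.five_extra_len + self.canonical_len:]

    def zone_of(self, zone: Zone) -> str:
        return {
            Zone.FIVE_EXTRA: self.five_extra_seq,
            Zone.CANONICAL: self.canonical_seq,
            Zone.THREE_EXTRA: self.three_extra_seq,
        }[zone]


def partition_genome(
    seq: ViralSequence,
    anchor_5: str = "GAAAAA",
    anchor_3: str = "CCATATGC",
    reference: GenomePartition | None = None,
    max_extra: int = 400,
) -> GenomePartition:
    """Split *seq* into 5'-extra / canonical / 3'-extra zones.

    With a *reference* (an already-partitioned homologous genome), zone
    boundaries are projected through a global nucleotide alignment; this
    takes precedence over motif anchoring. Otherwise the canonical zone
    starts at the anchor_5 occurrence that maximises canonical length while
    keeping the 5'-extra within *max_extra* nt (extras are short relative to
    the genome), and ends at the 3' terminus of the anchor_3 occurrence
    chosen by the mirror-image rule.
    """
    if reference is not None:
        return _partition_by_reference(seq, reference)

    hits5 = _occurrences(seq.residues, anchor_5)
    hits5 = [h for h in hits5 if h <= max_extra]
    if not hits5:
        raise UnanchorableError(
            f"{seq.id}: anchor_5 {anchor_5!r} not found within {max_extra} nt of the 5' end"
        )
    start = hits5[0]  # maximises canonical_len

    hits3 = _occurrences(seq.residues, anchor_3)
    hits3 = [
        h + len(anchor_3)
        for h in hits3
        if h >= start and seq.length - (h + len(anchor_3)) <= max_extra
    ]
    if not hits3:
        raise UnanchorableError(
            f"{seq.id}: anchor_3 {anchor_3!r} not found within {max_extra} nt of the 3' end"
        )
    end = hits3[-1]  # maximises canonical_len

    return GenomePartition(
        sequence=seq,
        five_extra_len=start,
        canonical_len=end - start,
        three_extra_len=seq.length - end,
        anchor_5=anchor_5,
        anchor_3=anchor_3,
        anchor_method="motif",
    )


def _occurrences(hay: str, needle: str) -> list[int]:
    if not needle or "N" in needle:
        raise PartitionError("anchors must be non-empty and N-free")
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _partition_by_reference(seq: ViralSequence, reference: GenomePartition) -> GenomePartition:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    try:
        aln = aligner.align(reference.sequence.residues, seq.residues)[0]
    except Exception as exc:  # pragma: no cover - pathological inputs
        raise UnanchorableError(f"{seq.id}: reference alignment failed: {exc}") from exc

    # Map reference boundary positions onto the query through the alignment.
    ref_start = reference.five_extra_len
    ref_end = ref_start + reference.canonical_len
    start = _project(aln, ref_start)
    end = _project(aln, ref_end)
    if end <= start:
        raise UnanchorableError(f"{seq.id}: canonical zone lost in reference alignment")
    return GenomePartition(
        sequence=seq,
        five_extra_len=start,
        canonical_len=end - start,
        three_extra_len=seq.length - end,
        anchor_5=reference.anchor_5,
        anchor_3=reference.anchor_3,
        anchor_method="reference_alignment",
    )


def _project(aln, ref_pos: int) -> int:
    """Project a 0-based reference boundary through a pairwise alignment."""
    ref_blocks, qry_blocks = aln.aligned
    for (rs, re), (qs, qe) in zip(ref_blocks, qry_blocks):
        if rs <= ref_pos < re:
            return qs + (ref_pos - rs)
        if ref_pos < rs:
            return qs
    return int(qry_blocks[-1][1]) if len(qry_blocks) else 0


# ---------------------------------------------------------------------------
# Paper-style coordinates


def to_paper_coord(p: GenomePartition, absolute_index: int) -> PaperCoordinate:
    """Map a 1-based absolute position to a zone-qualified coordinate."""
    if not 1 <= absolute_index <= p.sequence.length:
        raise CoordinateError(f"coordinate out of bounds: {absolute_index}")
    if absolute_index <= p.five_extra_len:
        return PaperCoordinate(Zone.FIVE_EXTRA, -(p.five_extra_len - absolute_index + 1))
    can_end = p.five_extra_len + p.canonical_len
    if absolute_index <= can_end:
        return PaperCoordinate(Zone.CANONICAL, absolute_index - p.five_extra_len)
    return PaperCoordinate(Zone.THREE_EXTRA, absolute_index - can_end)


def from_paper_coord(p: GenomePartition, c: PaperCoordinate) -> int:
    """Inverse of :func:`to_paper_coord`; returns a 1-based absolute position."""
    if c.zone is Zone.FIVE_EXTRA:
        if not -p.five_extra_len <= c.index <= -1:
            raise CoordinateError(f"coordinate out of bounds: {c}")
        return p.five_extra_len + c.index + 1
    if c.zone is Zone.CANONICAL:
        if not 1 <= c.index <= p.canonical_len:
            raise CoordinateError(f"coordinate out of bounds: {c}")
        return p.five_extra_len + c.index
    if not 1 <= c.index <= p.three_extra_len:
        raise CoordinateError(f"coordinate out of bounds: {c}")
    return p.five_extra_len + p.canonical_len + c.index


def span_length(p: GenomePartition, start: PaperCoordinate, end: PaperCoordinate) -> int:
    """Closed-interval nucleotide count between two coordinates.

    Crosses zone boundaries transparently, e.g. (-)14 .. 37 spans 51 nt.
    """
    a = from_paper_coord(p, start)
    b = from_paper_coord(p, end)
    if b < a:
        raise CoordinateError(f"negative span: {start} .. {end}")
    return b - a + 1


def coord_string(p: GenomePartition, absolute_index: int) -> str:
    """Paper-style label like ``C(-)14`` or ``A37`` for a 1-based position."""
    base = p.sequence.residues[absolute_index - 1]
    return f"{base}{to_paper_coord(p, absolute_index)}"


# ---------------------------------------------------------------------------
# Reports


def partition_report(p: GenomePartition) -> dict:
    return {
        "id": p.sequence.id,
        "length": p.sequence.length,
        "five_extra_len": p.five_extra_len,
        "canonical_len": p.canonical_len,
        "three_extra_len": p.three_extra_len,
        "anchor_5": p.anchor_5,
        "anchor_3": p.anchor_3,
        "anchor_method": p.anchor_method,
    }


def partition_json(p: GenomePartition) -> str:
    return json.dumps(partition_report(p), indent=2)


def partition_gff3_features(p: GenomePartition) -> list[tuple]:
    """Three ``region`` features (1-based inclusive) for GFF3 output."""
    feats = []
    a, b = p.five_extra_len, p.five_extra_len + p.canonical_len
    if a:
        feats.append((p.sequence.id, "region", 1, a, {"ID": "five_extra", "zone": "FIVE_EXTRA"}))
    feats.append((p.sequence.id, "region", a + 1, b, {"ID": "canonical", "zone": "CANONICAL"}))
    if p.three_extra_len:
        feats.append(
            (p.sequence.id, "region", b + 1, p.sequence.length,
             {"ID": "three_extra", "zone": "THREE_EXTRA"})
        )
    return feats
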