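"""Minimal GFF3 writer (1-based inclusive coordinates, 9 tab-separated
columns) for partitions, ORF/frameshift annotations and signal features."""

from __future__ import annotations

from .orfs import GagPolModel
from .partition import GenomePartition, partition_gff3_features
from .signals import SignalAnnotation

SOURCE = "lagenome"


def _attr(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items()) or "."


def _line(seqid: str, ftype: str, start: int, end: int, attrs: dict,
          score: str = ".", strand: str = "+", phase: str = ".") -> str:
    if not 1 <= start <= end:
        raise ValueError(f"bad GFF3 interval {start}-{end}")
    return "\t".join(
        [seqid, SOURCE, ftype, str(start), str(end), score, strand, phase, _attr(attrs)]
    )


def gff3_document(
    p: GenomePartition,
    gp: GagPolModel | None = None,
    signals: list[SignalAnnotation] | None = None,
) -> str:
    seqid = p.sequence.id
    lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {p.sequence.length}"]
    for sid, ftype, start, end, attrs in partition_gff3_features(p):
        lines.append(_line(sid, ftype, start, end, attrs))
    off = p.five_extra_len  # canonical -> absolute
    if gp is not None:
        lines.append(
            _line(seqid, "CDS", gp.gag.start + off, gp.gag.end + off,
                  {"ID": "gag", "frame": gp.gag.frame}, phase="0")
        )
        lines.append(
            _line(seqid, "CDS", gp.pol.start + off, gp.pol.end + off,
                  {"ID": "pol", "frame": gp.pol.frame,
                   "reinit_codons": ",".join(map(str, gp.reinit_codons)) or "none"},
                  phase="0")
        )
        lines.append(
            _line(seqid, "sequence_feature",
                  gp.slippery.position + off, gp.slippery.position + 6 + off,
                  {"ID": "slippery_site", "heptamer": gp.slippery.heptamer})
        )
    for s in signals or []:
        attrs = {"ID": s.kind.value.lower(), "kind": s.kind.value}
        if s.note:
            attrs["note"] = s.note.replace(";", ",")
        lines.append(_line(seqid, "sequence_feature", s.start + off, s.end + off, attrs))
    return "\n".join(lines) + "\n"
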