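"""Discovery of the conserved cis signals on a partitioned, annotated genome.

Five signal kinds are annotated on the canonical zone:

* FIVE_PRIME_MOTIF: the conserved 5' motif (GAAAAA, or its AATTAA homolog)
  at canonical position 1.
* AU_RICH: the most AU-rich 15-nt window of the 5' UTR, thought to help
  melt the duplex for conservative transcription.
* FRAMESHIFT_SL: the stimulatory hairpin starting within a short spacer
  3' of the slippery heptamer.
* PACKAGING_SL: the ~24-nt hairpin in the 3' half of the canonical zone
  bound by Pol for (+)-strand encapsidation. Because the loop sequence is
  the conserved determinant (the stem is not), candidates are ranked by
  loop identity to a reference packaging loop when one is supplied, and by
  free energy otherwise.
* REPLICATION_SL: the 3'-terminal hairpin required for (-)-strand synthesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

from .energy import EnergyModel, default_model
from .fold import Hairpin, enumerate_hairpins, fold_hairpin
from .orfs import GagPolModel
from .partition import GenomePartition, PaperCoordinate, to_paper_coord


class SignalKind(Enum):
    FIVE_PRIME_MOTIF = "FIVE_PRIME_MOTIF"
    AU_RICH = "AU_RICH"
    FRAMESHIFT_SL = "FRAMESHIFT_SL"
    PACKAGING_SL = "PACKAGING_SL"
    REPLICATION_SL = "REPLICATION_SL"


@dataclass(frozen=True)
class SignalAnnotation:
    kind: SignalKind
    start: int  # canonical 1-based, inclusive
    end: int
    hairpin: Hairpin | None = None
    note: str = ""

    def paper_span(self, p: GenomePartition) -> tuple[PaperCoordinate, PaperCoordinate]:
        off = p.five_extra_len
        return (to_paper_coord(p, self.start + off), to_paper_coord(p, self.end + off))


def max_au_window(seq: str, width: int = 15) -> tuple[int, float]:
    """(1-based start, AU fraction) of the most A/T-rich *width*-mer; the
    5'-most window wins ties."""
    if len(seq) < width:
        raise ValueError(f"sequence shorter than window ({width})")
    best_start, best_count = 1, -1
    count = sum(1 for c in seq[:width] if c in "AT")
    for start in range(len(seq) - width + 1):
        if start:
            count += (seq[start + width - 1] in "AT") - (seq[start - 1] in "AT")
        if count > best_count:
            best_start, best_count = start + 1, count
    return best_start, best_count / width


def _best_hairpin_in_window(
    seq: str, lo: int, hi: int, model: EnergyModel,
    min_span: int | None = None, max_span: int | None = None,
    ref_loop: str | None = None,
    window: int = 44, step: int = 15,
) -> tuple[Hairpin, int] | None:
    """Best hairpin folded from sliding windows over canonical [lo, hi]
    (1-based inclusive). Returns (hairpin, 1-based canonical offset of the
    window) with indices local to that window.

    Ranking: loop identity to *ref_loop* first when given, then dG; span
    length constrained to [min_span, max_span] when given. Interior loops
    are capped at 12 nt in this scan (a speed bound; MFE stem loops of the
    sizes scanned for essentially never use larger interior loops).
    """
    best = None
    for wstart in range(lo - 1, max(lo, hi - 4), step):
        wend = min(wstart + window, hi)
        sub = seq[wstart:wend]
        if len(sub) < 5:
            continue
        for hp in enumerate_hairpins(
            sub, model, suboptimality_percent=40, max_count=15, max_two_loop=12
        ):
            span = hp.span[1] - hp.span[0] + 1
            if min_span and span < min_span:
                continue
            if max_span and span > max_span:
                continue
            if ref_loop:
                ident = _loop_identity(hp.loop_seq, ref_loop)
                key = (-ident, hp.dG_kcal)
            else:
                key = (0, hp.dG_kcal)
            cand = (key, hp, wstart + 1)
            if best is None or cand[0] < best[0] or (
                cand[0] == best[0]
                and (cand[2] + hp.span[0]) < (best[2] + best[1].span[0])
            ):
                best = cand
        if wend == hi:
            break
    if best is None:
        return None
    return best[1], best[2]


def _loop_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y)
    return m / max(len(a), len(b))


def find_signal_stemloops(
    p: GenomePartition,
    gp: GagPolModel | None,
    ref_signals: list[SignalAnnotation] | None = None,
    model: EnergyModel | None = None,
    motif: str | None = None,
    frameshift_spacer: int = 12,
    packaging_span: tuple[int, int] = (20, 30),
    replication_window: int = 40,
) -> list[SignalAnnotation]:
    """Annotate the five conserved signals on the canonical zone.

    A missing slippery site (gp None) skips FRAMESHIFT_SL with a warning.
    """
    model = model or default_model()
    seq = p.canonical_seq
    out: list[SignalAnnotation] = []

    # 5' conserved motif within canonical 1-10
    m = motif or p.anchor_5 or "GAAAAA"
    idx = seq[:10 + len(m)].find(m)
    if 0 <= idx < 10:
        out.append(
            SignalAnnotation(SignalKind.FIVE_PRIME_MOTIF, idx + 1, idx + len(m), note=m)
        )

    # AU-rich 15-mer in the 5' UTR
    utr_end = gp.gag.start - 1 if gp else min(60, len(seq))
    if utr_end >= 15:
        start, frac = max_au_window(seq[:utr_end])
        out.append(
            SignalAnnotation(
                SignalKind.AU_RICH, start, start + 14, note=f"AU fraction {frac:.3f}"
            )
        )

    # frameshift hairpin: starts within `frameshift_spacer` nt 3' of the heptamer
    if gp is None:
        warnings.warn("no slippery site: skipping FRAMESHIFT_SL")
    else:
        lo = gp.slippery.position + 7
        hi = min(len(seq), lo + frameshift_spacer + 60)
        sub = seq[lo - 1: hi]
        best = None
        for hp in enumerate_hairpins(
            sub, model, suboptimality_percent=40, max_count=25, max_two_loop=12
        ):
            if hp.span[0] <= frameshift_spacer:
                if best is None or hp.dG_kcal < best.dG_kcal:
                    best = hp
        if best is not None:
            out.append(
                SignalAnnotation(
                    SignalKind.FRAMESHIFT_SL,
                    lo + best.span[0], lo + best.span[1],
                    hairpin=best,
                    note=f"dG {best.dG_kJ:.1f} kJ/mol",
                )
            )

    # packaging hairpin: best 20-30 nt stem loop in the 3' half
    ref_loop = None
    if ref_signals:
        for s in ref_signals:
            if s.kind is SignalKind.PACKAGING_SL and s.hairpin is not None:
                ref_loop = s.hairpin.loop_seq
    half = len(seq) // 2
    found = _best_hairpin_in_window(
        seq, half + 1, len(seq), model,
        min_span=packaging_span[0], max_span=packaging_span[1], ref_loop=ref_loop,
    )
    if found:
        hp, off = found
        out.append(
            SignalAnnotation(
                SignalKind.PACKAGING_SL,
                off + hp.span[0], off + hp.span[1],
                hairpin=hp,
                note=f"dG {hp.dG_kJ:.1f} kJ/mol",
            )
        )

    # replication hairpin: wholly within the last `replication_window` canonical nt
    tail_lo = max(1, len(seq) - replication_window + 1)
    hp = fold_hairpin(seq[tail_lo - 1:], model)
    if hp is not None:
        out.append(
            SignalAnnotation(
                SignalKind.REPLICATION_SL,
                tail_lo + hp.span[0], tail_lo + hp.span[1],
                hairpin=hp,
                note=f"dG {hp.dG_kJ:.1f} kJ/mol",
            )
        )
    return out
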