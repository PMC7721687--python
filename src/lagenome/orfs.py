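"""Gag / Pol ORF annotation and the -1 programmed ribosomal frameshift.

LA totiviruses translate Pol only as a Gag-Pol fusion: the ribosome slips
one nucleotide backwards at a slippery heptamer (XXXYYYZ, e.g. GGGUUUA)
just upstream of the Gag stop codon and continues in the -1 frame through
the Pol ORF. This module finds the ORFs, the heptamer, the in-frame
re-initiation ATGs between the Gag stop and Pol, and reconstructs the
fusion protein at residue level.

Conventions: ORF ``start``/``end`` are 1-based canonical positions of the
first nucleotide of the ATG and the last nucleotide *before* the stop codon
(the stop codon is excluded); ``frame`` is ``(start - 1) % 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq


class AnnotationError(ValueError):
    pass


class NoGagError(AnnotationError):
    pass


class NoFrameshiftSiteError(AnnotationError):
    pass


class NoPolError(AnnotationError):
    pass


@dataclass(frozen=True)
class OrfAnnotation:
    start: int
    end: int
    frame: int
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) != 3 * len(self.protein):
            raise AnnotationError("ORF span inconsistent with protein length")
        if "*" in self.protein:
            raise AnnotationError("internal stop in ORF protein")


@dataclass(frozen=True)
class SlipperySite:
    position: int  # canonical 1-based position of the heptamer's first base
    heptamer: str

    @property
    def X(self) -> str:
        return self.heptamer[0]

    @property
    def Y(self) -> str:
        return self.heptamer[3]

    @property
    def Z(self) -> str:
        return self.heptamer[6]


@dataclass(frozen=True)
class GagPolModel:
    gag: OrfAnnotation
    pol: OrfAnnotation
    slippery: SlipperySite
    fusion_protein: str
    reinit_codons: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pol.frame != (self.gag.frame - 1) % 3:
            raise AnnotationError("pol frame is not -1 relative to gag")
        if not self.slippery.position < self.gag.end:
            raise AnnotationError("slippery site not upstream of gag stop")
        n = _gag_prefix_len(self)
        if not self.fusion_protein.startswith(self.gag.protein[:n]):
            raise AnnotationError("fusion protein does not begin with a gag prefix")


def _gag_prefix_len(m: GagPolModel) -> int:
    return (m.slippery.position + 6 - m.gag.start + 1) // 3


def translate(seq: str, frame: int = 0) -> str:
    """Standard-code translation of one forward frame; stops rendered ``*``,
    trailing partial codon dropped."""
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def find_orfs(canonical_seq: str, min_protein_len: int = 100) -> list[OrfAnnotation]:
    """ATG-initiated, stop-terminated ORFs in the three forward frames.

    One ORF per (frame, stop codon): the reading starts at the first ATG
    following the previous stop in that frame. Sorted by start position.
    """
    orfs = []
    n = len(canonical_seq)
    for frame in range(3):
        start_codon = None
        for pos in range(frame, n - 2, 3):
            codon = canonical_seq[pos: pos + 3]
            if codon == "ATG" and start_codon is None:
                start_codon = pos
            elif codon in ("TAA", "TAG", "TGA"):
                if start_codon is not None:
                    protein = translate(canonical_seq[start_codon:pos])
                    if len(protein) >= min_protein_len:
                        orfs.append(
                            OrfAnnotation(
                                start=start_codon + 1,
                                end=pos,
                                frame=frame,
                                protein=protein,
                            )
                        )
                start_codon = None
    return sorted(orfs, key=lambda o: (o.start, -len(o.protein)))


def detect_slippery_sites(
    canonical_seq: str,
    window: tuple[int, int] | None = None,
    strict: bool = True,
) -> list[SlipperySite]:
    """All XXXYYYZ slippery heptamers in *window* (1-based, inclusive), 5'->3'.

    In strict mode (default) Y must be A or T and Z must not be G, matching
    canonical -1 PRF heptamers such as GGGUUUA; ``strict=False`` scans for
    the bare XXXYYYZ pattern.
    """
    lo, hi = window if window else (1, len(canonical_seq))
    if not (1 <= lo <= hi <= len(canonical_seq)):
        raise AnnotationError(f"window {window} outside sequence")
    sites = []
    for i in range(lo - 1, min(hi, len(canonical_seq)) - 6):
        h = canonical_seq[i: i + 7]
        if h[0] == h[1] == h[2] and h[3] == h[4] == h[5]:
            if strict and (h[3] not in "AT" or h[6] == "G"):
                continue
            sites.append(SlipperySite(position=i + 1, heptamer=h))
    return sites


def build_gagpol_model(
    partition_or_seq,
    min_gag_len: int = 400,
    min_pol_len: int = 100,
) -> GagPolModel:
    """Annotate Gag, the slippery site, Pol and the Gag-Pol fusion protein.

    * gag: the 5'-most ORF of Gag-like size (>= *min_gag_len* residues).
    * slippery: the strict heptamer nearest to, and upstream of, gag's stop.
    * pol: the longest ORF in frame (gag.frame - 1) mod 3 overlapping or
      following the slippery site.
    * fusion: gag codons ending at or before the heptamer's last base, then
      the -1-frame translation resuming one nucleotide 5' of the next gag
      codon boundary, through to the Pol stop.
    * reinit_codons: putative re-initiation starts — in-frame (pol frame)
      ATGs strictly after the gag stop and 5' of the Pol catalytic domain
      (operationalised as the first third of the Pol ORF). The Pol ORF's
      own start ATG qualifies: Pol is normally made only as the fusion, so
      every one of these ATGs is a candidate re-initiation codon.
    """
    seq = partition_or_seq if isinstance(partition_or_seq, str) else partition_or_seq.canonical_seq

    candidates = [o for o in find_orfs(seq, min_protein_len=min_gag_len)]
    if not candidates:
        raise NoGagError(f"no gag: no ORF of >= {min_gag_len} residues")
    gag = candidates[0]

    sites = detect_slippery_sites(seq, window=(gag.start, gag.end))
    sites = [s for s in sites if s.position < gag.end]
    if not sites:
        raise NoFrameshiftSiteError("no frameshift site upstream of the gag stop")
    slippery = sites[-1]

    pol_frame = (gag.frame - 1) % 3
    pol_candidates = [
        o
        for o in find_orfs(seq, min_protein_len=min_pol_len)
        if o.frame == pol_frame and o.end > slippery.position
    ]
    if not pol_candidates:
        raise NoPolError("no pol: no compatible -1-frame ORF")
    pol = max(pol_candidates, key=lambda o: len(o.protein))

    n_prefix = (slippery.position + 6 - gag.start + 1) // 3
    resume = gag.start + 3 * n_prefix - 1  # one nt 5' of the next gag codon
    shifted = translate(seq[resume - 1:])
    stop_at = shifted.find("*")
    suffix = shifted if stop_at == -1 else shifted[:stop_at]
    fusion = gag.protein[:n_prefix] + suffix

    domain_start = pol.start + (pol.end - pol.start + 1) // 3
    reinit = tuple(
        q + 1
        for q in range(gag.end, domain_start - 1)
        if q % 3 == pol_frame and seq[q: q + 3] == "ATG"
    )

    return GagPolModel(
        gag=gag, pol=pol, slippery=slippery, fusion_protein=fusion, reinit_codons=reinit
    )
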