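"""Synthetic LA-like genomes with complete planted ground truth.

The generator emits a (+)-strand cDNA with the canonical LA architecture:
a 5' conserved motif at canonical position 1, an AU-rich 15-mer in the 5'
UTR, a Gag ORF, an XXXYYYZ slippery heptamer with an adjacent GC-stem
hairpin, a -1-frame Pol ORF with re-initiation ATGs, a 24-nt packaging
hairpin in the 3' half, a 3'-terminal replication hairpin, and 5'/3'
extra sequences carrying planted self-identity copies, a near-palindromic
boundary stem loop and (optionally) a host-like fragment. Every planted
feature is recorded in a :class:`SyntheticTruth` so annotation output can
be compared field by field.

Construction strategy: fixed feature blocks are written into a scratch
array, free positions are drawn uniformly, tied positions (self-identity
copies) mirror their source, and a deterministic repair pass then removes
any chance stop codons / spurious ATGs / spurious slippery heptamers from
the constrained reading frames. Hairpin stems are GC-only with A/C loops,
which keeps them stop-free in every frame and makes their folding
recovery unambiguous at the default energy parameters.

Families are evolved along a guide tree under Jukes-Cantor substitutions
(and optional indels), with mutations masked out of protected feature
intervals by default so that per-leaf truth stays valid.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .sequences import ViralSequence, reverse_complement
from .partition import GenomePartition, partition_genome
from .orfs import build_gagpol_model

STOPS = ("TAA", "TAG", "TGA")
BASES = "ACGT"


class LayoutError(ValueError):
    pass


@dataclass
class GenomeParams:
    """Layout of a synthetic LA-like genome (canonical coords, 1-based).

    The defaults reproduce the TdV-LAbarr1 geometry: 14 + 4591 + 17 nt,
    AATTAA / CCATAAGC anchors, Gag from nt 61, slippery heptamer GGGTTTA,
    and a 51-nt self-identity stretch straddling the 5' boundary whose
    central 31-mer is a near-palindromic stem loop.
    """

    virus_id: str = "synLA1"
    five_extra_len: int = 14
    canonical_len: int = 4591
    three_extra_len: int = 17
    anchor_5: str = "AATTAA"
    anchor_3: str = "CCATAAGC"
    gag_start: int = 61
    gag_aa: int = 677
    slippery_codon_offset: int = 640  # heptamer starts at this gag codon
    slippery: str = "GGGTTTA"
    pol_start: int = 2376
    pol_aa: int = 725
    reinit_internal_offset: int = 120  # nt after pol_start of the internal ATG
    au_rich_start: int = 40
    frameshift_spacer: int = 5
    frameshift_arms: str = "GGCGCGGCC"
    frameshift_loop: str = "GCAA"
    packaging_start: int = 4205
    packaging_arms: str = "GGCGCCGGCC"
    packaging_loop: str = "ACAA"
    replication_start: int = 4560
    replication_arms: str = "GGCGCC"
    replication_loop: str = "AAC"
    plant_boundary_palindrome: bool = True  # the 31-mer across the 5' boundary
    five_self_identity: bool = True  # 51-nt copy (-)14..37 -> canonical interior
    five_target_start: int = 400  # canonical start of the 5' self-identity copy
    three_self_identity: bool = True  # 16-nt copy (+)2..(+)17 -> pol interior
    three_target_start: int = 4457
    host_fragment_len: int = 0  # >0 plants a host-like fragment in the 5' extra
    host_divergence: float = 0.0
    host_id: str = "synthetic-18S-rRNA"

    @property
    def gag_end(self) -> int:
        return self.gag_start + 3 * self.gag_aa - 1

    @property
    def slippery_pos(self) -> int:
        return self.gag_start + 3 * self.slippery_codon_offset

    @property
    def pol_end(self) -> int:
        return self.pol_start + 3 * self.pol_aa - 1


# The stem loop printed for the 5' boundary of TdV-LAbarr1: 14 extra nt +
# the first 17 canonical nt (loop AATT = canonical 1-4).
BOUNDARY_31MER = "CACGTAGCTTTATTAATTAATATGCTACGTG"


@dataclass
class SyntheticTruth:
    """Planted ground truth; all coordinates 1-based (canonical unless
    marked absolute)."""

    virus_id: str
    seed: int
    five_extra_len: int
    canonical_len: int
    three_extra_len: int
    anchor_5: str
    anchor_3: str
    gag_start: int
    gag_end: int
    gag_protein: str
    slippery_pos: int
    slippery_heptamer: str
    pol_start: int
    pol_end: int
    pol_protein: str
    reinit_codons: tuple[int, ...]
    fusion_protein: str
    five_motif_span: tuple[int, int]
    au_rich_span: tuple[int, int]
    au_rich_fraction: float
    frameshift_sl_span: tuple[int, int]
    packaging_sl_span: tuple[int, int]
    packaging_loop: str
    replication_sl_span: tuple[int, int]
    self_identity_five: tuple[int, int, int, int] | None  # abs q_start,q_end,s_start,s_end
    self_identity_three: tuple[int, int, int, int] | None
    palindrome_abs_span: tuple[int, int] | None
    host_fragment: dict | None
    protected_abs_intervals: tuple[tuple[int, int], ...]  # 0-based half-open

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class FamilySpec:
    """Guide tree with per-branch expected substitutions/site."""

    newick: str
    indel_rate: float = 0.0  # per-site per-branch
    indel_mean_len: float = 2.0
    protect_features: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# construction helpers


def _check_layout(p: GenomeParams) -> None:
    fs_start = p.slippery_pos + 7 + p.frameshift_spacer
    fs_end = fs_start + 2 * len(p.frameshift_arms) + len(p.frameshift_loop) - 1
    pk_end = p.packaging_start + 2 * len(p.packaging_arms) + len(p.packaging_loop) - 1
    rp_end = p.replication_start + 2 * len(p.replication_arms) + len(p.replication_loop) - 1
    ok = (
        p.gag_start > max(54, p.au_rich_start + 15)
        and p.gag_end + 3 < p.pol_start
        and p.slippery_pos + 6 < p.gag_end - 2
        and fs_end < p.gag_end
        and p.packaging_start > p.canonical_len // 2
        and pk_end < p.canonical_len
        and p.pol_end + 3 < p.replication_start
        and p.canonical_len - 40 < p.replication_start
        and rp_end < p.canonical_len - len(p.anchor_3)
        and (p.pol_start - 1) % 3 == (p.gag_start - 2) % 3
    )
    if p.packaging_start <= p.pol_end:
        # packaging hairpin inside pol coding is the realistic layout
        ok = ok and pk_end <= p.pol_end
    if not ok:
        raise LayoutError("layout infeasible")
    if p.five_self_identity:
        tgt_lo = p.five_target_start
        tgt_hi = tgt_lo + p.five_extra_len + 37 - 1
        if not (p.gag_start + 3 < tgt_lo and tgt_hi < p.slippery_pos - 10):
            raise LayoutError("layout infeasible: 5' self-identity target must sit inside gag")
        if p.plant_boundary_palindrome and (tgt_lo - p.gag_start) % 3 != 0:
            # the boundary 31-mer is stop-free only in its own frame 0, so its
            # copy must land on a gag codon boundary
            raise LayoutError("layout infeasible: 5' self-identity target out of gag phase")
    if p.three_self_identity and not (
        p.pol_start < p.three_target_start and p.three_target_start + 15 < p.pol_end
        and p.three_extra_len >= 17
    ):
        raise LayoutError("layout infeasible: 3' self-identity placement")
    if p.plant_boundary_palindrome and (
        p.five_extra_len != 14 or not p.anchor_5 == BOUNDARY_31MER[14:20]
    ):
        raise LayoutError("layout infeasible: boundary palindrome needs the 14-nt extra and AATTAA anchor")
    if p.host_fragment_len and p.host_fragment_len > p.five_extra_len - 5:
        raise LayoutError("layout infeasible: host fragment exceeds the 5' extra")


class _Builder:
    def __init__(self, p: GenomeParams, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self.n = p.five_extra_len + p.canonical_len + p.three_extra_len
        self.seq = [""] * self.n
        self.fixed = np.zeros(self.n, dtype=bool)
        self.tied: dict[int, int] = {}  # target abs0 -> source abs0
        self.protected: list[tuple[int, int]] = []  # 0-based half-open, abs

    # -- coordinates --
    def abs0(self, canonical_1based: int) -> int:
        return self.p.five_extra_len + canonical_1based - 1

    def place(self, abs0: int, block: str, protect: bool = True) -> None:
        for k, ch in enumerate(block):
            if self.fixed[abs0 + k] and self.seq[abs0 + k] != ch:
                raise LayoutError(
                    f"layout infeasible: feature collision at {abs0 + k}"
                )
            self.seq[abs0 + k] = ch
            self.fixed[abs0 + k] = True
        if protect:
            self.protected.append((abs0, abs0 + len(block)))

    def place_can(self, canonical_1based: int, block: str, protect: bool = True) -> None:
        self.place(self.abs0(canonical_1based), block, protect)

    def fill_free(self) -> None:
        draws = self.rng.integers(0, 4, size=self.n)
        for i in range(self.n):
            if not self.seq[i]:
                self.seq[i] = BASES[draws[i]]

    def mirror_ties(self) -> None:
        for tgt, src in self.tied.items():
            self.seq[tgt] = self.seq[src]

    def mutate(self, i: int, forbidden: set[str]) -> None:
        """Rewrite a mutable base (resolving ties to the source)."""
        if i in self.tied:
            i = self.tied[i]
        if self.fixed[i]:
            raise LayoutError("layout infeasible: constraint hits a fixed base")
        choices = [b for b in BASES if b != self.seq[i] and b not in forbidden]
        self.seq[i] = choices[int(self.rng.integers(0, len(choices)))]
        self.mirror_ties()

    def mutable_in(self, lo: int, hi: int) -> list[int]:
        return [
            i for i in range(lo, hi)
            if (not self.fixed[i]) or (i in self.tied and not self.fixed[self.tied[i]])
        ]


def _codon_scan(seq: str, start0: int, end0: int, phase_anchor0: int):
    """Triplet starts in [start0, end0-2] aligned with phase_anchor0."""
    first = start0 + ((phase_anchor0 - start0) % 3)
    return range(first, end0 - 1, 3)


def _strict_heptamer(s: str) -> bool:
    return (
        len(s) == 7
        and s[0] == s[1] == s[2]
        and s[3] == s[4] == s[5]
        and s[3] in "AT"
        and s[6] != "G"
    )


def simulate_genome(
    params: GenomeParams | None = None, seed: int = 0
) -> tuple[ViralSequence, SyntheticTruth]:
    """Emit a genome plus its truth record; deterministic per seed.

    A handful of sub-seeded attempts are made so that rare chance
    collisions (e.g. a duplicate anchor occurrence in random filler) are
    resolved deterministically.
    """
    params = params or GenomeParams()
    _check_layout(params)
    last_err: Exception | None = None
    for attempt in range(10):
        try:
            return _simulate_once(params, seed, attempt)
        except LayoutError as exc:
            last_err = exc
    raise LayoutError(f"could not realise layout for seed {seed}: {last_err}")


def _simulate_once(p: GenomeParams, seed: int, attempt: int) -> tuple[ViralSequence, SyntheticTruth]:
    rng = np.random.default_rng([seed, attempt, 20201123])
    b = _Builder(p, rng)
    fe = p.five_extra_len

    # -- fixed feature blocks --------------------------------------------
    b.place_can(1, p.anchor_5)
    b.place_can(p.canonical_len - len(p.anchor_3) + 1, p.anchor_3)

    palindrome_span = None
    if p.plant_boundary_palindrome:
        b.place(0, BOUNDARY_31MER)
        palindrome_span = (11, 22)  # near-palindrome arms within the 31-mer

    # AU-rich 15-mer with GC guards so the max-AU window is unique
    au = "".join("AT"[int(x)] for x in rng.integers(0, 2, size=15))
    b.place_can(p.au_rich_start - 1, "C" + au + "G")
    au_fraction = 1.0

    # Gag: upstream in-frame stop, ATG, stop codon
    b.place_can(p.gag_start - 3, "TAA", protect=False)
    b.place_can(p.gag_start, "ATG")
    b.place_can(p.gag_end + 1, "TAA")

    # slippery heptamer at gag codon boundary; -1-frame stop just upstream
    h = p.slippery_pos
    b.place_can(h, p.slippery)
    b.place_can(h - 4, "TAA", protect=False)

    # frameshift hairpin a short spacer 3' of the heptamer
    fs_start = h + 7 + p.frameshift_spacer
    fs_hp = p.frameshift_arms + p.frameshift_loop + reverse_complement(p.frameshift_arms)
    b.place_can(fs_start, fs_hp)
    fs_span = (fs_start, fs_start + len(fs_hp) - 1)

    # Pol ORF: ATG, internal re-initiation ATG, stop
    b.place_can(p.pol_start, "ATG")
    reinit_internal = p.pol_start + p.reinit_internal_offset
    b.place_can(reinit_internal, "ATG")
    b.place_can(p.pol_end + 1, "TAA")

    # packaging hairpin with non-pairing C guards
    pk_hp = p.packaging_arms + p.packaging_loop + reverse_complement(p.packaging_arms)
    b.place_can(p.packaging_start - 1, "C" + pk_hp + "C")
    pk_span = (p.packaging_start, p.packaging_start + len(pk_hp) - 1)

    # replication hairpin in the 3'-terminal window
    rp_hp = p.replication_arms + p.replication_loop + reverse_complement(p.replication_arms)
    b.place_can(p.replication_start - 1, "C" + rp_hp + "C")
    rp_span = (p.replication_start, p.replication_start + len(rp_hp) - 1)

    # host-like fragment in the 5' extra
    host_record = None
    host_info = None
    if p.host_fragment_len:
        host_res = "".join(BASES[i] for i in rng.integers(0, 4, size=max(600, p.host_fragment_len + 50)))
        host_record = ViralSequence(id=p.host_id, residues=host_res, description="synthetic host sequence")
        frag = list(host_res[20: 20 + p.host_fragment_len])
        n_div = int(round(p.host_divergence * len(frag)))
        div_sites = rng.choice(len(frag), size=n_div, replace=False) if n_div else []
        for s in div_sites:
            frag[s] = [x for x in BASES if x != frag[s]][int(rng.integers(0, 3))]
        b.place(0, "".join(frag))
        host_info = {
            "host_id": p.host_id,
            "length": p.host_fragment_len,
            "query_span": (1, p.host_fragment_len),
            "subject_span": (21, 20 + p.host_fragment_len),
            "divergence": p.host_divergence,
            "host_residues": host_res,
        }

    # -- free fill and self-identity ties --------------------------------
    b.fill_free()

    self_five = None
    if p.five_self_identity:
        # copy absolute 1..fe+37 (the (-)fe..37 stretch) into the gag interior,
        # mirroring the published 51-nt self-identity of the 5' boundary
        src_lo, src_len = 0, fe + 37
        tgt_lo = b.abs0(p.five_target_start)
        for k in range(src_len):
            if b.fixed[tgt_lo + k]:
                raise LayoutError("layout infeasible: self-identity target collides")
            b.tied[tgt_lo + k] = src_lo + k
        b.protected.append((src_lo, src_lo + src_len))
        b.protected.append((tgt_lo, tgt_lo + src_len))
        self_five = (1, src_len, tgt_lo + 1, tgt_lo + src_len)

    self_three = None
    if p.three_self_identity:
        src_lo = fe + p.canonical_len + 1  # (+)2, 0-based
        tgt_lo = b.abs0(p.three_target_start)
        for k in range(16):
            if b.fixed[tgt_lo + k]:
                raise LayoutError("layout infeasible: 3' self-identity target collides")
            b.tied[tgt_lo + k] = src_lo + k
        b.protected.append((src_lo, src_lo + 16))
        b.protected.append((tgt_lo, tgt_lo + 16))
        self_three = (src_lo + 1, src_lo + 16, tgt_lo + 1, tgt_lo + 16)

    b.mirror_ties()
    _repair(b)
    seq_str = "".join(b.seq)

    genome = ViralSequence(
        id=p.virus_id, residues=seq_str, description="synthetic LA-like genome"
    )

    # -- derive sequence-dependent truth fields --------------------------
    can = seq_str[fe: fe + p.canonical_len]
    gag_protein = _translate(can[p.gag_start - 1: p.gag_end])
    pol_protein = _translate(can[p.pol_start - 1: p.pol_end])
    n_prefix = (h + 6 - p.gag_start + 1) // 3
    resume = p.gag_start + 3 * n_prefix - 1
    shifted = _translate(can[resume - 1:])
    fusion = gag_protein[:n_prefix] + shifted[: shifted.find("*")]

    protected = tuple(sorted(b.protected))
    truth = SyntheticTruth(
        virus_id=p.virus_id,
        seed=seed,
        five_extra_len=fe,
        canonical_len=p.canonical_len,
        three_extra_len=p.three_extra_len,
        anchor_5=p.anchor_5,
        anchor_3=p.anchor_3,
        gag_start=p.gag_start,
        gag_end=p.gag_end,
        gag_protein=gag_protein,
        slippery_pos=h,
        slippery_heptamer=p.slippery,
        pol_start=p.pol_start,
        pol_end=p.pol_end,
        pol_protein=pol_protein,
        reinit_codons=(p.pol_start, reinit_internal),
        fusion_protein=fusion,
        five_motif_span=(1, len(p.anchor_5)),
        au_rich_span=(p.au_rich_start, p.au_rich_start + 14),
        au_rich_fraction=au_fraction,
        frameshift_sl_span=fs_span,
        packaging_sl_span=pk_span,
        packaging_loop=p.packaging_loop.replace("T", "U"),
        replication_sl_span=rp_span,
        self_identity_five=self_five,
        self_identity_three=self_three,
        palindrome_abs_span=palindrome_span,
        host_fragment=host_info,
        protected_abs_intervals=protected,
    )
    _verify_light(genome, truth, p)
    return genome, truth


def _translate(nt: str) -> str:
    from .orfs import translate

    return translate(nt)


def _repair(b: _Builder) -> None:
    """Deterministically remove chance stops / spurious ATGs / spurious
    slippery heptamers from the constrained frames, and enforce the
    flank-mismatch guards that keep planted exact matches maximal."""
    p = b.p
    fe = p.five_extra_len
    gag0 = b.abs0(p.gag_start)
    gag_end0 = b.abs0(p.gag_end)
    h0 = b.abs0(p.slippery_pos)
    pol0 = b.abs0(p.pol_start)
    pol_end0 = b.abs0(p.pol_end)
    domain0 = pol0 + (pol_end0 - pol0 + 1) // 3
    allowed_atg = {pol0, b.abs0(p.pol_start + p.reinit_internal_offset)}

    for _ in range(600):
        viol = _first_violation(b, gag0, gag_end0, h0, pol0, pol_end0, domain0, allowed_atg)
        if viol is None:
            break
        kind, lo, hi = viol
        mutable = b.mutable_in(lo, hi)
        if not mutable:
            raise LayoutError(f"layout infeasible: immutable {kind} at {lo}")
        i = mutable[-1]
        b.mutate(i, forbidden=set())
    else:
        raise LayoutError("layout infeasible: repair did not converge")

    # maximality guards for the planted self-identity copies
    for tgt, src in _tie_flanks(b):
        if 0 <= tgt < b.n and 0 <= src < b.n and b.seq[tgt] == b.seq[src]:
            which = tgt if not b.fixed[tgt] else src
            if b.fixed[which] and which not in b.tied:
                raise LayoutError("layout infeasible: fixed guard flank")
            b.mutate(which, forbidden={b.seq[src if which == tgt else tgt]})
            if _first_violation(b, gag0, gag_end0, h0, pol0, pol_end0, domain0, allowed_atg):
                _repair(b)  # re-run; terminates because guards are re-checked
                return


def _tie_flanks(b: _Builder):
    """(target_flank, source_flank) absolute pairs that must differ."""
    out = []
    if not b.tied:
        return out
    # group tied runs
    targets = sorted(b.tied)
    run_start = targets[0]
    prev = targets[0]
    for t in targets[1:] + [None]:
        if t is None or t != prev + 1 or b.tied[t] != b.tied[prev] + 1:
            src_start = b.tied[run_start]
            src_end = b.tied[prev]
            out.append((run_start - 1, src_start - 1))
            out.append((prev + 1, src_end + 1))
            if t is not None:
                run_start = t
        prev = t if t is not None else prev
    return [(a, s) for a, s in out if 0 <= a < b.n and 0 <= s < b.n]


def _first_violation(b, gag0, gag_end0, h0, pol0, pol_end0, domain0, allowed_atg):
    s = "".join(b.seq)
    # gag frame: no stops inside the ORF
    for t in _codon_scan(s, gag0, gag_end0 + 1, gag0):
        if s[t: t + 3] in STOPS:
            return ("gag-frame stop", t, t + 3)
    # fusion/pol frame: no stops from just after the heptamer to the pol stop
    for t in _codon_scan(s, h0 + 4, pol_end0 + 1, pol0):
        if s[t: t + 3] in STOPS:
            return ("pol-frame stop", t, t + 3)
    # pol frame: no spurious ATG between gag stop and the pol domain
    for t in _codon_scan(s, gag_end0 + 4, domain0, pol0):
        if t not in allowed_atg and s[t: t + 3] == "ATG":
            return ("spurious reinit ATG", t, t + 3)
    # the planted slippery heptamer must be the only strict one in gag
    for t in range(gag0, gag_end0 - 6):
        if t != h0 and _strict_heptamer(s[t: t + 7]):
            return ("spurious slippery heptamer", t, t + 7)
    return None


def _verify_light(genome: ViralSequence, truth: SyntheticTruth, p: GenomeParams) -> None:
    """Cheap invariant checks; a failure triggers a new sub-seeded attempt."""
    part = partition_genome(genome, anchor_5=p.anchor_5, anchor_3=p.anchor_3)
    if (part.five_extra_len, part.canonical_len, part.three_extra_len) != (
        truth.five_extra_len, truth.canonical_len, truth.three_extra_len
    ):
        raise LayoutError("partition recovery failed")
    gp = build_gagpol_model(part)
    if (gp.gag.start, gp.gag.end) != (truth.gag_start, truth.gag_end):
        raise LayoutError("gag recovery failed")
    if gp.slippery.position != truth.slippery_pos:
        raise LayoutError("slippery recovery failed")
    if (gp.pol.start, gp.pol.end) != (truth.pol_start, truth.pol_end):
        raise LayoutError("pol recovery failed")
    if gp.fusion_protein != truth.fusion_protein:
        raise LayoutError("fusion recovery failed")
    if tuple(gp.reinit_codons) != tuple(truth.reinit_codons):
        raise LayoutError("reinit recovery failed")


# ---------------------------------------------------------------------------
# presets


def preset(name: str) -> GenomeParams:
    """Named layouts mirroring the sequenced-genome geometries."""
    if name == "labarr1":
        return GenomeParams()
    if name == "la1":
        return GenomeParams(
            virus_id="synLA1original", five_extra_len=252, canonical_len=4580,
            three_extra_len=42, anchor_5="GAAAAA", anchor_3="CCATATGC",
            plant_boundary_palindrome=False, three_self_identity=False,
            pol_aa=715, packaging_start=4200, replication_start=4545,
        )
    if name == "lalus4":
        # the 5' extra carries a host rRNA-like fragment instead of a
        # self-identity copy, as in the sequenced genome
        return GenomeParams(
            virus_id="synLAlus4", five_extra_len=187, canonical_len=4580,
            three_extra_len=9, anchor_5="GAAAAA", anchor_3="CCATATGC",
            plant_boundary_palindrome=False, five_self_identity=False,
            three_self_identity=False, host_fragment_len=178,
            pol_aa=715, packaging_start=4200, replication_start=4545,
        )
    raise KeyError(name)


# ---------------------------------------------------------------------------
# family evolution


def evolve_family(
    genome: ViralSequence,
    truth: SyntheticTruth,
    spec: FamilySpec,
) -> tuple[dict[str, ViralSequence], dict[str, SyntheticTruth], str]:
    """Evolve *genome* along the guide tree; returns (leaf sequences,
    per-leaf truth, the true tree in Newick).

    Substitutions are Jukes-Cantor: each unprotected site changes with
    probability 3/4 (1 - exp(-4t/3)) on a branch of length t expected
    substitutions/site. Indels (optional) are drawn per site with
    geometric lengths and never touch protected intervals.
    """
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(spec.newick))
    leaves = list(tree.tips())
    if len(leaves) < 3:
        raise ValueError("spec tree needs >= 3 leaves")
    rng = np.random.default_rng([spec.seed, 77])
    protected = np.zeros(len(genome.residues), dtype=bool)
    if spec.protect_features:
        for lo, hi in truth.protected_abs_intervals:
            protected[lo:hi] = True

    out_seqs: dict[str, ViralSequence] = {}
    out_truth: dict[str, SyntheticTruth] = {}

    def descend(node, residues: str, prot: np.ndarray, tr: SyntheticTruth):
        for child in node.children:
            t = child.length or 0.0
            child_res, child_prot, child_tr = _mutate_branch(residues, t, prot, tr, rng, spec)
            if child.is_tip():
                name = child.name or f"leaf{len(out_seqs) + 1}"
                out_seqs[name] = ViralSequence(
                    id=name, residues=child_res,
                    description=f"descendant of {genome.id}",
                )
                out_truth[name] = SyntheticTruth(**{**asdict(child_tr), "virus_id": name})
            else:
                descend(child, child_res, child_prot, child_tr)

    descend(tree, genome.residues, protected, truth)
    return out_seqs, out_truth, spec.newick


def _coding_constraints(truth: SyntheticTruth):
    """Frame constraints implied by the genome architecture, as
    (kind, frame_anchor0, lo0, hi0) with 0-based absolute half-open
    intervals: Gag must stay stop-free, the fusion/Pol frame must stay
    stop-free from the frameshift to the Pol stop, and no new ATG may
    appear in the re-initiation window."""
    fe = truth.five_extra_len
    gag0 = fe + truth.gag_start - 1
    gag_end0 = fe + truth.gag_end - 1
    pol0 = fe + truth.pol_start - 1
    pol_end0 = fe + truth.pol_end - 1
    h0 = fe + truth.slippery_pos - 1
    domain0 = pol0 + (pol_end0 - pol0 + 1) // 3
    return [
        ("no_stop", gag0, gag0, gag_end0 + 1),
        ("no_stop", pol0, h0 + 5, pol_end0 + 1),
        ("no_atg", pol0, gag_end0 + 4, domain0),
    ], (gag0, pol_end0 + 4)


def _violates(seq: list, i: int, constraints) -> bool:
    """Does the base at *i* sit in a forbidden codon of any constraint?"""
    for kind, anchor, lo, hi in constraints:
        if not lo <= i < hi:
            continue
        t = i - ((i - anchor) % 3)
        if t < lo or t + 3 > hi:
            continue
        codon = "".join(seq[t: t + 3])
        if kind == "no_stop" and codon in STOPS:
            return True
        if kind == "no_atg" and codon == "ATG":
            return True
    return False


def _mutate_branch(residues: str, t: float, protected: np.ndarray, truth: SyntheticTruth,
                   rng, spec: FamilySpec):
    """One branch of evolution; returns (sequence, protection mask, truth)
    with coordinates remapped through any indel events.

    Substitutions respect the coding architecture: a draw that would
    create a stop in the Gag or fusion frame (or a spurious ATG in the
    re-initiation window) picks another base, or is skipped. Indels are
    restricted to non-coding regions so reading frames stay intact.
    """
    n = len(residues)
    seq = list(residues)
    constraints, coding = _coding_constraints(truth)
    if t > 0:
        p_change = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
        hits = np.nonzero((rng.random(n) < p_change) & ~protected[:n])[0]
        for i in hits:
            old = seq[i]
            alts = [b for b in BASES if b != old]
            rng.shuffle(alts)
            for b in alts:
                seq[i] = b
                if not _violates(seq, i, constraints):
                    break
            else:
                seq[i] = old
    events: list[tuple[int, int]] = []  # (0-based pos in branch input, +ins/-del length)
    if spec.indel_rate > 0:
        indel_ok = ~protected[:n].copy()
        indel_ok[coding[0]: coding[1]] = False
        sites = np.nonzero((rng.random(n) < spec.indel_rate) & indel_ok)[0]
        for i in sorted(sites, reverse=True):
            length = int(1 + rng.geometric(1.0 / spec.indel_mean_len))
            if rng.random() < 0.5:  # deletion, clipped to the indel-safe run
                j = i
                while j < min(n, i + length) and indel_ok[j]:
                    j += 1
                if j > i:
                    del seq[i:j]
                    events.append((i, -(j - i)))
            else:
                ins = "".join(BASES[k] for k in rng.integers(0, 4, size=length))
                seq[i:i] = list(ins)
                events.append((i, length))
    out = "".join(seq)
    if not events:
        return out, protected, truth
    events.sort()
    new_prot = np.zeros(len(out), dtype=bool)
    old_prot_pos = np.nonzero(protected[:n])[0]
    for pos in old_prot_pos:
        new_prot[_map0(events, pos)] = True
    return out, new_prot, _remap_truth(truth, events, n)


def _map0(events: list[tuple[int, int]], pos0: int) -> int:
    """Map a 0-based position through sorted indel events (positions are in
    the branch-input coordinate system; deleted positions map to the cut)."""
    shift = 0
    for i, delta in events:
        if delta < 0:
            if pos0 >= i - delta:  # beyond the deleted run
                shift += delta
            elif pos0 >= i:  # inside the deleted run
                return i + shift
        elif i <= pos0:
            shift += delta
    return pos0 + shift


def _remap_truth(truth: SyntheticTruth, events, old_len: int) -> SyntheticTruth:
    d = asdict(truth)
    old_fe = truth.five_extra_len
    old_can = truth.canonical_len
    new_fe = _map0(events, old_fe)
    new_can_end = _map0(events, old_fe + old_can)
    new_len = len_after(events, old_len)
    d["five_extra_len"] = new_fe
    d["canonical_len"] = new_can_end - new_fe
    d["three_extra_len"] = new_len - new_can_end

    def can_map(c1: int) -> int:  # canonical 1-based through the events
        return _map0(events, old_fe + c1 - 1) - new_fe + 1

    def abs_map(a1: int) -> int:  # absolute 1-based
        return _map0(events, a1 - 1) + 1

    for key in ("gag_start", "gag_end", "slippery_pos", "pol_start", "pol_end"):
        d[key] = can_map(d[key])
    d["reinit_codons"] = tuple(can_map(x) for x in truth.reinit_codons)
    for key in ("five_motif_span", "au_rich_span", "frameshift_sl_span",
                "packaging_sl_span", "replication_sl_span"):
        lo, hi = d[key]
        d[key] = (can_map(lo), can_map(hi))
    for key in ("self_identity_five", "self_identity_three"):
        if d[key] is not None:
            d[key] = tuple(abs_map(x) for x in d[key])
    if d["palindrome_abs_span"] is not None:
        d["palindrome_abs_span"] = tuple(abs_map(x) for x in d["palindrome_abs_span"])
    d["protected_abs_intervals"] = tuple(
        (_map0(events, lo), _map0(events, hi - 1) + 1)
        for lo, hi in truth.protected_abs_intervals
    )
    return SyntheticTruth(**d)


def len_after(events, old_len: int) -> int:
    return old_len + sum(delta for _, delta in events)
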