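"""Characterisation of the 5'/3' extra sequences.

HTS-derived LA genomes run past the canonical termini. The extra zones
show three recurring features: stretches 100% identical to the canonical
interior of the same genome (viral self-identity), stretches shared
between the extras of different viruses, and near-palindromes that fold
into terminal stem loops; some extras also carry host fragments (rRNA,
chromosomal DNA). Exact-match searches are seed-and-extend over 13-mers;
their contract is fixed by quadratic brute-force oracles in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .partition import GenomePartition, Zone, coord_string
from .sequences import ViralSequence, reverse_complement

DEFAULT_MIN_LEN = 13  # shortest shared stretch reported for these genomes
CANONICAL_FLANK = 60  # self-identity windows may run into the canonical zone


@dataclass(frozen=True)
class SelfIdentityMatch:
    """Exact repeat between an extra-zone window and the canonical interior.

    Spans are 1-based inclusive absolute positions on the full sequence.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    length: int
    identity: float = 100.0

    def __post_init__(self) -> None:
        if self.query_end - self.query_start != self.subject_end - self.subject_start:
            raise ValueError("query and subject spans differ in length")
        if not (self.query_end < self.subject_start or self.subject_end < self.query_start):
            raise ValueError("query and subject spans overlap")

    def paper_string(self, p: GenomePartition) -> str:
        return (
            f"{coord_string(p, self.query_start)}-{coord_string(p, self.query_end)}"
            f" to {coord_string(p, self.subject_start)}-{coord_string(p, self.subject_end)}"
        )


@dataclass(frozen=True)
class SharedStretch:
    virus_a: str
    virus_b: str
    stretch: str
    start_a: int  # 1-based absolute on genome a
    start_b: int

    @property
    def length(self) -> int:
        return len(self.stretch)


@dataclass(frozen=True)
class PalindromeHit:
    start: int  # 1-based inclusive, full span including loop
    end: int
    arm_len: int
    loop_len: int
    mismatches: int


@dataclass(frozen=True)
class HostHit:
    host_id: str
    identity: float
    length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 < self.identity <= 100:
            raise ValueError("identity out of range")


# ---------------------------------------------------------------------------
# exact-match machinery


def _maximal_matches(a: str, b: str, min_len: int, a_off: int, b_off: int):
    """Maximal exact matches >= min_len between strings a and b, reported as
    (start_a, start_b, length) in absolute 0-based coordinates (offsets
    added). Seed-and-extend over min_len-mers; maximality enforced by
    discarding extensible or contained seeds."""
    if min_len < 1 or len(a) < min_len or len(b) < min_len:
        return []
    seeds: dict[str, list[int]] = {}
    for i in range(len(a) - min_len + 1):
        seeds.setdefault(a[i: i + min_len], []).append(i)
    found = {}
    for j in range(len(b) - min_len + 1):
        kmer = b[j: j + min_len]
        for i in seeds.get(kmer, ()):  # extend each seed to its maximal match
            li, lj = i, j
            while li > 0 and lj > 0 and a[li - 1] == b[lj - 1]:
                li, lj = li - 1, lj - 1
            ri, rj = i + min_len, j + min_len
            while ri < len(a) and rj < len(b) and a[ri] == b[rj]:
                ri, rj = ri + 1, rj + 1
            found[(li + a_off, lj + b_off, ri - li)] = True
    # drop matches contained in a longer one on the same diagonal
    out = []
    by_diag: dict[int, list[tuple[int, int, int]]] = {}
    for (sa, sb, ln) in found:
        by_diag.setdefault(sa - sb, []).append((sa, sb, ln))
    for diag_matches in by_diag.values():
        diag_matches.sort(key=lambda m: (m[0], -m[2]))
        last_end = -1
        for sa, sb, ln in diag_matches:
            if sa + ln > last_end:
                out.append((sa, sb, ln))
                last_end = sa + ln
    return out


def find_self_identity(
    p: GenomePartition,
    min_len: int = DEFAULT_MIN_LEN,
    canonical_flank: int = CANONICAL_FLANK,
) -> list[SelfIdentityMatch]:
    """Maximal exact matches between extra-zone windows and the canonical
    interior of the same genome, longest first.

    Query windows are each extra zone plus up to *canonical_flank* nt of
    adjacent canonical sequence (reported self-identities straddle the
    boundary); query and subject absolute spans must be disjoint.
    """
    if p.five_extra_len == 0 and p.three_extra_len == 0:
        raise ValueError("no extra zones to search")
    full = p.sequence.residues
    can_start = p.five_extra_len  # 0-based
    can_end = can_start + p.canonical_len
    queries = []
    if p.five_extra_len:
        queries.append((0, min(can_start + canonical_flank, can_end)))
    if p.three_extra_len:
        queries.append((max(can_end - canonical_flank, can_start), len(full)))
    subject = full[can_start:can_end]

    matches = []
    for qlo, qhi in queries:
        for sa, sb, ln in _maximal_matches(
            full[qlo:qhi], subject, min_len, qlo, can_start
        ):
            if sa == sb:  # the trivial self-alignment
                continue
            # require disjoint absolute intervals
            if not (sa + ln <= sb or sb + ln <= sa):
                continue
            matches.append(
                SelfIdentityMatch(
                    query_start=sa + 1, query_end=sa + ln,
                    subject_start=sb + 1, subject_end=sb + ln,
                    length=ln,
                )
            )
    uniq = {(m.query_start, m.subject_start, m.length): m for m in matches}
    return sorted(uniq.values(), key=lambda m: (-m.length, m.query_start))


def find_shared_stretches(
    p_a: GenomePartition,
    p_b: GenomePartition,
    zone: Zone = Zone.FIVE_EXTRA,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[SharedStretch]:
    """Maximal common substrings >= *min_len* between the selected extra
    zone of two genomes, longest first."""
    a, b = p_a.zone_of(zone), p_b.zone_of(zone)
    if not a or not b:
        raise ValueError(f"zone {zone.value} empty in one of the genomes")
    off_a = 0 if zone is Zone.FIVE_EXTRA else (
        p_a.five_extra_len if zone is Zone.CANONICAL
        else p_a.five_extra_len + p_a.canonical_len
    )
    off_b = 0 if zone is Zone.FIVE_EXTRA else (
        p_b.five_extra_len if zone is Zone.CANONICAL
        else p_b.five_extra_len + p_b.canonical_len
    )
    out = [
        SharedStretch(
            virus_a=p_a.sequence.id,
            virus_b=p_b.sequence.id,
            stretch=p_a.sequence.residues[sa: sa + ln],
            start_a=sa + 1,
            start_b=sb + 1,
        )
        for sa, sb, ln in _maximal_matches(a, b, min_len, off_a, off_b)
    ]
    return sorted(out, key=lambda s: (-s.length, s.start_a))


def palindrome_scan(
    seq: str,
    min_arm: int = 8,
    max_loop: int = 8,
    max_mismatch: int = 2,
) -> list[PalindromeHit]:
    """Maximal reverse-complement arm pairs (near-palindromes).

    A hit is left arm + loop (0..max_loop nt) + right arm, where the right
    arm is the reverse complement of the left up to *max_mismatch*
    substitutions and arms are >= *min_arm*. Hits whose span lies within
    another hit's span are suppressed.
    """
    n = len(seq)
    hits = []
    for loop in range(0, max_loop + 1):
        for mid in range(n):  # left arm ends at mid-1, loop occupies [mid, mid+loop)
            right_start = mid + loop
            # extend arms outward, tracking mismatches; record maximal arms
            arm, mism = 0, 0
            best = None
            while mid - arm - 1 >= 0 and right_start + arm < n:
                l = seq[mid - arm - 1]
                r = seq[right_start + arm]
                if reverse_complement(l) != r:
                    mism += 1
                    if mism > max_mismatch:
                        break
                arm += 1
                # arms must not end on a mismatch
                if arm >= min_arm and reverse_complement(seq[mid - arm]) == seq[right_start + arm - 1]:
                    best = (arm, mism)
            if best:
                arm, mism = best
                hits.append(
                    PalindromeHit(
                        start=mid - arm + 1,
                        end=right_start + arm,
                        arm_len=arm,
                        loop_len=loop,
                        mismatches=mism,
                    )
                )
    # non-redundant: drop hits contained in another hit's span
    hits.sort(key=lambda h: (h.start - 1, -(h.end)))
    kept: list[PalindromeHit] = []
    for h in sorted(hits, key=lambda h: -(h.end - h.start)):
        if any(k.start <= h.start and h.end <= k.end and k != h for k in kept):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end))


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def match_host_sequences(
    p: GenomePartition,
    zone: Zone,
    host_db: list[ViralSequence],
    min_len: int = 50,
    min_identity: float = 85.0,
    canonical_flank: int = CANONICAL_FLANK,
) -> list[HostHit]:
    """Smith-Waterman (affine gaps, both strands) of an extra zone (plus a
    short canonical flank) against candidate host sequences.

    Identity = identical columns / alignment columns x 100. rRNA hits on
    the (-) strand are reported with strand "-".
    """
    if not host_db:
        raise ValueError("no host records")
    full = p.sequence.residues
    can_start, can_end = p.five_extra_len, p.five_extra_len + p.canonical_len
    if zone is Zone.FIVE_EXTRA:
        qlo, qhi = 0, min(can_start + canonical_flank, len(full))
    elif zone is Zone.THREE_EXTRA:
        qlo, qhi = max(can_end - canonical_flank, 0), len(full)
    else:
        qlo, qhi = can_start, can_end
    query = full[qlo:qhi]
    if not query:
        return []

    aligner = _local_aligner()
    hits = []
    for rec in host_db:
        for strand, subject in (("+", rec.residues), ("-", reverse_complement(rec.residues))):
            alns = aligner.align(query, subject)
            if len(alns) == 0:
                continue
            cols = _alignment_columns(alns[0], query, subject)
            seg = _best_identity_segment(cols, min_identity)
            if seg is None:
                continue
            lo, hi = seg  # half-open column interval
            length = hi - lo
            if length < min_len:
                continue
            matches = sum(1 for c in cols[lo:hi] if c[2])
            identity = 100.0 * matches / length
            if identity < min_identity:
                continue
            q_cols = [c[0] for c in cols[lo:hi] if c[0] is not None]
            s_cols = [c[1] for c in cols[lo:hi] if c[1] is not None]
            s_start, s_end = s_cols[0], s_cols[-1] + 1
            if strand == "-":  # report subject span on the + strand
                s_start, s_end = len(rec.residues) - s_end, len(rec.residues) - s_start
            hits.append(
                HostHit(
                    host_id=rec.id,
                    identity=round(identity, 1),
                    length=int(length),
                    query_start=int(qlo + q_cols[0] + 1),
                    query_end=int(qlo + q_cols[-1] + 1),
                    subject_start=int(s_start + 1),
                    subject_end=int(s_end),
                    strand=strand,
                )
            )
    return sorted(hits, key=lambda h: (-h.length, -h.identity))


def _alignment_columns(aln, query: str, subject: str):
    """Expand a Biopython alignment into (qpos|None, spos|None, is_match)
    columns, including gap columns between aligned blocks."""
    qb, sb = aln.aligned
    cols = []
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qb, sb):
        if prev_q is not None:
            for q in range(prev_q, qs):
                cols.append((q, None, False))
            for s in range(prev_s, ss):
                cols.append((None, s, False))
        for k in range(qe - qs):
            cols.append((qs + k, ss + k, query[qs + k] == subject[ss + k]))
        prev_q, prev_s = qe, se
    return cols


def _best_identity_segment(cols, min_identity: float):
    """Maximal-scoring column interval under +1/match and a penalty chosen
    so that any optimal segment has identity >= roughly *min_identity*
    (Kadane). Trims the over-extended tails local alignment produces when
    a high-identity block is flanked by unrelated sequence."""
    if not cols:
        return None
    penalty = min_identity / max(100.0 - min_identity, 1e-9)
    best = None
    run_score, run_start = 0.0, 0
    for idx, c in enumerate(cols):
        score = 1.0 if c[2] else -penalty
        if run_score <= 0:
            run_score, run_start = score, idx
        else:
            run_score += score
        if run_score > 0 and (best is None or run_score > best[0]):
            best = (run_score, run_start, idx + 1)
    if best is None:
        return None
    return best[1], best[2]
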