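import numpy as np
import pytest

from lagenome import (
    GenomePartition,
    ViralSequence,
    Zone,
    find_self_identity,
    find_shared_stretches,
    match_host_sequences,
    palindrome_scan,
)
from lagenome.simulate import GenomeParams, preset, simulate_genome

from .oracles import brute_force_maximal_matches, brute_force_palindromes

PRINTED_31MER = "CACGTAGCTTTATTAATTAATATGCTACGTG"
SHARED_13MER = "GACAAGTCCTCCG"  # the 13-nt stretch shared by two 5' extras


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _partition_with_extras(extra5, canonical, extra3, vid="v"):
    return GenomePartition(
        sequence=ViralSequence(id=vid, residues=extra5 + canonical + extra3),
        five_extra_len=len(extra5), canonical_len=len(canonical),
        three_extra_len=len(extra3), anchor_method="reference_alignment",
    )


class TestSelfIdentity:
    def test_planted_51nt_duplication(self, default_genome, default_partition):
        """The boundary-spanning 51-nt stretch is found as the single top
        match, at its planted coordinates."""
        _, truth = default_genome
        matches = find_self_identity(default_partition)
        top = matches[0]
        assert (top.query_start, top.query_end, top.subject_start, top.subject_end) == \
            truth.self_identity_five
        assert top.length == 51
        assert top.identity == 100.0
        # the 3' planted 16-mer is also reported
        assert truth.self_identity_three in [
            (m.query_start, m.query_end, m.subject_start, m.subject_end) for m in matches
        ]

    def test_matches_revalidate_and_are_maximal(self, default_partition):
        full = default_partition.sequence.residues
        for m in find_self_identity(default_partition):
            q = full[m.query_start - 1: m.query_end]
            s = full[m.subject_start - 1: m.subject_end]
            assert q == s
            left_q, left_s = m.query_start - 2, m.subject_start - 2
            if left_q >= 0 and left_s >= 0:
                assert full[left_q] != full[left_s]
            if m.query_end < len(full) and m.subject_end < len(full):
                assert full[m.query_end] != full[m.subject_end]

    def test_no_duplication_is_empty(self, plain_genome):
        genome, truth = plain_genome
        p = _partition_with_extras(
            genome.residues[:30], genome.residues[30:-25], genome.residues[-25:]
        )
        assert find_self_identity(p) == []

    def test_agrees_with_quadratic_oracle(self, default_genome, default_partition):
        p = default_partition
        full = p.sequence.residues
        can_start, can_end = p.five_extra_len, p.five_extra_len + p.canonical_len
        got = {
            (m.query_start - 1, m.subject_start - 1, m.length)
            for m in find_self_identity(p)
        }
        expected = set()
        for qlo, qhi in ((0, can_start + 60), (can_end - 60, len(full))):
            for sa, sb, ln in brute_force_maximal_matches(
                full[qlo:qhi], full[can_start:can_end], 13
            ):
                a, b = sa + qlo, sb + can_start
                if a != b and (a + ln <= b or b + ln <= a):
                    expected.add((a, b, ln))
        assert got == expected

    def test_requires_an_extra_zone(self):
        p = _partition_with_extras("", "ACGT" * 30, "")
        with pytest.raises(ValueError):
            find_self_identity(p)


class TestSharedStretches:
    def test_planted_13mer(self):
        rng = np.random.default_rng(31)
        # flank guards (A vs C) keep the planted 13-mer exactly maximal
        ex_a = _random_seq(rng, 19) + "A" + SHARED_13MER + "A" + _random_seq(rng, 9)
        ex_b = _random_seq(rng, 4) + "C" + SHARED_13MER + "C" + _random_seq(rng, 24)
        pa = _partition_with_extras(ex_a, _random_seq(rng, 100), "", vid="a")
        pb = _partition_with_extras(ex_b, _random_seq(rng, 100), "", vid="b")
        stretches = find_shared_stretches(pa, pb)
        assert stretches and stretches[0].stretch == SHARED_13MER
        assert stretches[0].start_a == 21 and stretches[0].start_b == 6

    def test_random_extras_share_nothing(self):
        rng = np.random.default_rng(37)
        pa = _partition_with_extras(_random_seq(rng, 60), _random_seq(rng, 50), "")
        pb = _partition_with_extras(_random_seq(rng, 60), _random_seq(rng, 50), "")
        assert find_shared_stretches(pa, pb, min_len=13) == []

    def test_agrees_with_oracle(self):
        rng = np.random.default_rng(41)
        base = _random_seq(rng, 40)
        ex_a = base[5:35] + _random_seq(rng, 30)
        ex_b = _random_seq(rng, 12) + base[10:38]
        pa = _partition_with_extras(ex_a, _random_seq(rng, 60), "", vid="a")
        pb = _partition_with_extras(ex_b, _random_seq(rng, 60), "", vid="b")
        got = {(s.start_a - 1, s.start_b - 1, s.length) for s in find_shared_stretches(pa, pb, min_len=8)}
        expected = set(brute_force_maximal_matches(ex_a, ex_b, 8))
        assert got == expected


class TestPalindromeScan:
    def test_constructed_perfect_palindrome(self):
        hits = palindrome_scan("GGGAATTCCC", min_arm=3, max_loop=4, max_mismatch=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.mismatches) == (1, 10, 0)

    def test_printed_31mer_near_palindrome(self):
        """The boundary stem loop region is nearly palindromic: its core
        shows up with relaxed arms and no substitution errors."""
        hits = palindrome_scan(PRINTED_31MER, min_arm=4, max_loop=8, max_mismatch=2)
        assert any(h.start <= 11 and h.end >= 22 and h.mismatches <= 2 for h in hits)

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(53)
        for _ in range(8):
            seq = _random_seq(rng, 60)
            got = {
                (h.start, h.end, h.arm_len, h.loop_len, h.mismatches)
                for h in palindrome_scan(seq, min_arm=3, max_loop=3, max_mismatch=1)
            }
            expected = set(brute_force_palindromes(seq, 3, 3, 1))
            assert got == expected, seq

    def test_no_hit_below_min_arm(self):
        assert palindrome_scan("ACGTACGTAC", min_arm=5, max_loop=2, max_mismatch=0) == []


class TestHostMatching:
    def test_planted_exact_fragment(self):
        g, t = simulate_genome(preset("lalus4"), seed=3)
        p = _partition_with_extras(
            g.residues[:187], g.residues[187:-9], g.residues[-9:]
        )
        host = ViralSequence(id=t.host_fragment["host_id"],
                             residues=t.host_fragment["host_residues"])
        hits = match_host_sequences(p, Zone.FIVE_EXTRA, [host])
        assert hits
        top = hits[0]
        assert top.identity == 100.0
        assert 178 <= top.length <= 182
        assert top.query_start <= 1 + 2 and top.query_end >= 178
        assert top.strand == "+"

    def test_diverged_fragment_identity_tracks_divergence(self):
        import dataclasses

        params = dataclasses.replace(preset("lalus4"), host_divergence=0.07)
        g, t = simulate_genome(params, seed=4)
        p = _partition_with_extras(g.residues[:187], g.residues[187:-9], g.residues[-9:])
        host = ViralSequence(id="h", residues=t.host_fragment["host_residues"])
        hits = match_host_sequences(p, Zone.FIVE_EXTRA, [host])
        assert hits
        assert 90.0 <= hits[0].identity <= 97.5  # ~93% planted, trimming biases up

    def test_minus_strand_hit(self):
        from lagenome.sequences import reverse_complement

        rng = np.random.default_rng(61)
        host_res = _random_seq(rng, 400)
        fragment = reverse_complement(host_res[100:220])
        p = _partition_with_extras(fragment + _random_seq(rng, 10),
                                   _random_seq(rng, 300), "")
        hits = match_host_sequences(p, Zone.FIVE_EXTRA, [ViralSequence(id="h", residues=host_res)])
        assert hits and hits[0].strand == "-"
        assert hits[0].identity == 100.0

    def test_unrelated_zone_is_empty(self, plain_genome):
        rng = np.random.default_rng(67)
        genome, _ = plain_genome
        p = _partition_with_extras(
            genome.residues[:30], genome.residues[30:-25], genome.residues[-25:]
        )
        host = ViralSequence(id="h", residues=_random_seq(rng, 500))
        assert match_host_sequences(p, Zone.FIVE_EXTRA, [host]) == []

    def test_empty_db_rejected(self, default_partition):
        with pytest.raises(ValueError, match="no host records"):
            match_host_sequences(default_partition, Zone.FIVE_EXTRA, [])
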