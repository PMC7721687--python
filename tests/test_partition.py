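import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagenome import (
    GenomePartition,
    PaperCoordinate,
    ViralSequence,
    Zone,
    from_paper_coord,
    partition_genome,
    span_length,
    to_paper_coord,
)
from lagenome.partition import CoordinateError, UnanchorableError, coord_string
from lagenome.simulate import GenomeParams, simulate_genome


def _parted(fe, can, te, seed=0):
    rng = np.random.default_rng(seed)
    res = "".join("ACGT"[i] for i in rng.integers(0, 4, size=fe + can + te))
    return GenomePartition(
        sequence=ViralSequence(id="x", residues=res),
        five_extra_len=fe, canonical_len=can, three_extra_len=te,
        anchor_method="reference_alignment",
    )


class TestPartitionGenome:
    def test_labarr1_geometry(self, default_genome):
        """The 4,622-nt genome splits 14 / 4,591 / 17 at its anchors."""
        genome, truth = default_genome
        p = partition_genome(genome, anchor_5="AATTAA", anchor_3="CCATAAGC")
        assert (p.five_extra_len, p.canonical_len, p.three_extra_len) == (14, 4591, 17)
        assert genome.length == 4622
        assert p.canonical_seq.startswith("AATTAA")

    def test_identity_case_no_extras(self):
        seq = ViralSequence(id="c", residues="GAAAAA" + "ACGT" * 20 + "CCATATGC")
        p = partition_genome(seq, anchor_5="GAAAAA", anchor_3="CCATATGC")
        assert (p.five_extra_len, p.three_extra_len) == (0, 0)
        assert p.canonical_len == seq.length

    def test_planted_extras_recovered(self):
        params = GenomeParams(
            five_extra_len=30, three_extra_len=25,
            plant_boundary_palindrome=False, three_self_identity=False,
            anchor_5="GAAAAA", anchor_3="CCATATGC",
        )
        genome, truth = simulate_genome(params, seed=4)
        p = partition_genome(genome, anchor_5="GAAAAA", anchor_3="CCATATGC")
        assert (p.five_extra_len, p.three_extra_len) == (30, 25)

    def test_reference_alignment_roundtrip(self, default_genome):
        """Projecting zones from a reference onto an unmutated copy
        reproduces the reference's zone lengths exactly."""
        genome, truth = default_genome
        ref = partition_genome(genome, anchor_5="AATTAA", anchor_3="CCATAAGC")
        again = partition_genome(genome, reference=ref)
        assert (again.five_extra_len, again.canonical_len, again.three_extra_len) == (
            ref.five_extra_len, ref.canonical_len, ref.three_extra_len
        )
        assert again.anchor_method == "reference_alignment"

    def test_unanchorable(self):
        seq = ViralSequence(id="u", residues="ACGT" * 30)
        with pytest.raises(UnanchorableError):
            partition_genome(seq, anchor_5="GAAAAA", anchor_3="CCATATGC")

    def test_zone_lengths_must_sum(self):
        seq = ViralSequence(id="z", residues="ACGT" * 10)
        with pytest.raises(ValueError):
            GenomePartition(sequence=seq, five_extra_len=1, canonical_len=10,
                            three_extra_len=1, anchor_method="reference_alignment")


class TestPaperCoordinates:
    """The signed convention: canonical 1..N, 5' extras (-)1..,
    3' extras (+)1.."""

    @pytest.mark.parametrize(
        "absolute,zone,index",
        [
            (15, Zone.CANONICAL, 1),
            (1, Zone.FIVE_EXTRA, -14),
            (14, Zone.FIVE_EXTRA, -1),
            (4605, Zone.CANONICAL, 4591),
            (4606, Zone.THREE_EXTRA, 1),
            (4622, Zone.THREE_EXTRA, 17),
        ],
    )
    def test_to_paper_coord(self, absolute, zone, index):
        p = _parted(14, 4591, 17)
        c = to_paper_coord(p, absolute)
        assert (c.zone, c.index) == (zone, index)
        assert from_paper_coord(p, c) == absolute

    @pytest.mark.parametrize(
        "zone,index,absolute",
        [
            (Zone.CANONICAL, 401, 415),
            (Zone.FIVE_EXTRA, -1, 14),
            (Zone.THREE_EXTRA, 2, 4607),
        ],
    )
    def test_from_paper_coord(self, zone, index, absolute):
        p = _parted(14, 4591, 17)
        assert from_paper_coord(p, PaperCoordinate(zone, index)) == absolute

    def test_roundtrip_bijection_random_partitions(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            fe, can, te = int(rng.integers(0, 30)), int(rng.integers(1, 200)), int(rng.integers(0, 30))
            p = _parted(fe, can, te, seed=int(rng.integers(0, 2**31)))
            seen = set()
            for a in range(1, p.sequence.length + 1):
                c = to_paper_coord(p, a)
                assert from_paper_coord(p, c) == a
                seen.add((c.zone, c.index))
            assert len(seen) == p.sequence.length  # bijective

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        fe=st.integers(0, 40),
        can=st.integers(1, 300),
        te=st.integers(0, 40),
        frac=st.floats(0.0, 1.0),
    )
    def test_roundtrip_property(self, fe, can, te, frac):
        seq = ViralSequence(id="h", residues="A" * (fe + can + te))
        p = GenomePartition(sequence=seq, five_extra_len=fe, canonical_len=can,
                            three_extra_len=te, anchor_method="reference_alignment")
        a = 1 + int(frac * (seq.length - 1))
        c = to_paper_coord(p, a)
        assert from_paper_coord(p, c) == a
        if c.zone is Zone.FIVE_EXTRA:
            assert -fe <= c.index <= -1
        elif c.zone is Zone.CANONICAL:
            assert 1 <= c.index <= can
        else:
            assert 1 <= c.index <= te

    def test_out_of_bounds(self):
        p = _parted(2, 10, 2)
        with pytest.raises(CoordinateError):
            to_paper_coord(p, 0)
        with pytest.raises(CoordinateError):
            to_paper_coord(p, 15)
        with pytest.raises(CoordinateError):
            from_paper_coord(p, PaperCoordinate(Zone.FIVE_EXTRA, -3))

    def test_coord_string_style(self):
        p = _parted(14, 4591, 17, seed=3)
        s = coord_string(p, 1)
        assert s.endswith("(-)14")


class TestSpanLength:
    def test_boundary_crossing_span_51(self):
        """(-)14 .. 37 crosses the 5' boundary and spans 51 nt."""
        p = _parted(14, 4591, 17)
        n = span_length(
            p, PaperCoordinate(Zone.FIVE_EXTRA, -14), PaperCoordinate(Zone.CANONICAL, 37)
        )
        assert n == 51

    def test_single_position(self):
        p = _parted(5, 50, 5)
        c = PaperCoordinate(Zone.CANONICAL, 7)
        assert span_length(p, c, c) == 1

    def test_la1_3prime_span_44(self):
        """Canonical 4,579 .. (+)42 on the LA1 geometry spans 44 nt."""
        p = _parted(252, 4580, 42)
        n = span_length(
            p, PaperCoordinate(Zone.CANONICAL, 4579), PaperCoordinate(Zone.THREE_EXTRA, 42)
        )
        assert n == 44

    def test_span_equals_coordinate_difference(self):
        p = _parted(10, 80, 10, seed=8)
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b = sorted(rng.integers(1, p.sequence.length + 1, size=2))
            ca, cb = to_paper_coord(p, int(a)), to_paper_coord(p, int(b))
            assert span_length(p, ca, cb) == b - a + 1

    def test_negative_span_rejected(self):
        p = _parted(5, 50, 5)
        with pytest.raises(CoordinateError):
            span_length(p, PaperCoordinate(Zone.CANONICAL, 10), PaperCoordinate(Zone.CANONICAL, 9))
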