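import io

import numpy as np
import pytest

from lagenome import (
    Region,
    RegionSpec,
    check_conserved_residues,
    extract_region,
    identity_matrix,
    nj_phylogram,
    pairwise_identity,
)
from lagenome.compare import CompareError, rdrp_third
from lagenome.simulate import FamilySpec, evolve_family, simulate_genome

from .oracles import three_taxon_branch_lengths


def _identity_from_distances(labels, dist):
    n = len(labels)
    values = np.full((n, n), 100.0)
    for (i, j), d in dist.items():
        values[i, j] = values[j, i] = 100.0 * (1 - d)
    return identity_matrix_from_values(labels, values)


def identity_matrix_from_values(labels, values):
    from lagenome.compare import IdentityMatrix

    return IdentityMatrix(labels=tuple(labels), values=values,
                          region=RegionSpec(Region.GAGPOL_AA))


class TestPairwiseIdentity:
    def test_self_is_100(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0
        assert pairwise_identity("MKVLA", "MKVLA", kind="AA") == 100.0

    def test_three_quarters(self):
        assert pairwise_identity("ACGT", "ACGA") == 75.0

    def test_symmetry(self):
        rng = np.random.default_rng(71)
        for _ in range(8):
            a = "".join(rng.choice(list("ACGT"), size=60))
            b = "".join(rng.choice(list("ACGT"), size=55))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(CompareError, match="empty"):
            pairwise_identity("", "ACGT")


class TestExtractRegion:
    def test_reference_returns_its_own_interval(self):
        ref = "MKVLAWQERTYIPASDFGHKL" * 10
        spec = RegionSpec(Region.VAR19_AA, (21, 39))
        assert extract_region(ref, ref, spec) == ref[20:39]

    def test_var44_span_enforced(self):
        with pytest.raises(CompareError):
            RegionSpec(Region.VAR44_AA, (729, 771))
        RegionSpec(Region.VAR44_AA, (729, 772))  # 44 residues, legal

    def test_projection_without_indels(self, eight_leaf_family):
        """With substitutions only, the projected region sits at the same
        coordinates in every family member."""
        seqs, truths, _, root_truth = eight_leaf_family
        a, b = seqs["A"].residues, seqs["B"].residues
        spec = RegionSpec(Region.CANONICAL_NT, (1001, 1200))
        got = extract_region(b, a, spec, kind="NT")
        assert got == b[1000:1200]

    def test_region_lost(self):
        """A target covering only the reference's 5' half cannot supply a
        3'-half region."""
        rng = np.random.default_rng(97)
        ref = "".join(rng.choice(list("ACGT"), size=400))
        target = ref[:100]
        with pytest.raises(CompareError, match="lost in alignment"):
            extract_region(target, ref, RegionSpec(Region.CANONICAL_NT, (350, 390)), "NT")

    def test_rdrp_third_is_central(self):
        pol = "A" * 30 + "B" * 30 + "C" * 30
        assert rdrp_third(pol) == "B" * 30


class TestIdentityMatrix:
    def test_structure_matches_planted_divergence(self, eight_leaf_family):
        seqs, _, _, _ = eight_leaf_family
        data = {k: seqs[k].residues for k in ("A", "B", "E")}
        m = identity_matrix(data, RegionSpec(Region.GENOME_NT))
        df = m.to_frame()
        assert df.loc["A", "B"] > df.loc["A", "E"]
        assert df.loc["A", "B"] > df.loc["B", "E"]
        assert np.allclose(np.diag(m.values), 100.0)
        assert np.allclose(m.values, m.values.T)

    def test_pair_consistency_with_pairwise(self):
        a, b = "ACGTACGTGG", "ACGTACGAGG"
        m = identity_matrix({"x": a, "y": b}, RegionSpec(Region.GENOME_NT))
        assert m.values[0, 1] == pairwise_identity(a, b)

    def test_needs_two(self):
        with pytest.raises(CompareError):
            identity_matrix({"x": "ACGT"}, RegionSpec(Region.GENOME_NT))


class TestConservedResidues:
    @staticmethod
    def _reference(rng):
        aa = list("".join(rng.choice(list("ARNDCEQGHILKMFPSTWYV"), size=700)))
        aa[149], aa[151], aa[153] = "Y", "D", "H"  # Tyr-150, Asp-152, His-154
        aa[451], aa[537] = "Y", "Y"
        return "".join(aa)

    def test_reference_against_itself(self):
        rng = np.random.default_rng(83)
        ref = self._reference(rng)
        panel = check_conserved_residues(
            ref, ref, motif_intervals={"A": (500, 520), "B": (530, 545)}
        )
        assert panel.h154 is True
        assert all(panel.cap_residues.values())
        assert all(v == 100.0 for v in panel.rdrp_motifs.values())

    def test_h154_mutation_detected(self):
        rng = np.random.default_rng(83)
        ref = self._reference(rng)
        mutated = ref[:153] + "A" + ref[154:]
        panel = check_conserved_residues(mutated, ref)
        assert panel.h154 is False
        assert all(panel.cap_residues.values())


class TestNjPhylogram:
    def test_three_taxa_closed_form(self):
        """NJ on three taxa reproduces the unique additive branch lengths."""
        from skbio import TreeNode

        d = {(0, 1): 0.2, (0, 2): 0.3, (1, 2): 0.4}
        m = _identity_from_distances(["A", "B", "C"], d)
        tree = TreeNode.read(io.StringIO(nj_phylogram(m).newick))
        # patristic distances must reproduce the additive input exactly,
        # which pins the closed-form branch lengths
        exp = three_taxon_branch_lengths(0.2, 0.3, 0.4)
        assert all(x >= 0 for x in exp)
        dist = {p: tree.find(p[0]).distance(tree.find(p[1]))
                for p in (("A", "B"), ("A", "C"), ("B", "C"))}
        assert dist[("A", "B")] == pytest.approx(exp[0] + exp[1])
        assert dist[("A", "C")] == pytest.approx(exp[0] + exp[2])
        assert dist[("B", "C")] == pytest.approx(exp[1] + exp[2])

    def test_equal_distances_star(self):
        d = {(i, j): 0.3 for i in range(4) for j in range(i + 1, 4)}
        m = _identity_from_distances(list("ABCD"), d)
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nj_phylogram(m).newick))
        dists = [tree.find(a).distance(tree.find(b))
                 for a in "ABCD" for b in "ABCD" if a < b]
        assert np.allclose(dists, 0.3)

    def test_too_few_taxa(self):
        m = _identity_from_distances(["A", "B"], {(0, 1): 0.1})
        with pytest.raises(CompareError, match="too few"):
            nj_phylogram(m)

    def test_recovers_eight_leaf_topology(self, eight_leaf_family):
        """NJ on genome-wide identities reproduces the generating topology
        (Robinson-Foulds distance 0) at low divergence."""
        import io as _io

        from skbio import TreeNode

        seqs, _, true_newick, _ = eight_leaf_family
        data = {k: v.residues for k, v in sorted(seqs.items())}
        m = identity_matrix(data, RegionSpec(Region.GENOME_NT))
        got = TreeNode.read(_io.StringIO(nj_phylogram(m).newick))
        want = TreeNode.read(_io.StringIO(true_newick))
        rf = got.compare_rfd(want)
        assert rf == 0.0

    def test_deterministic_under_label_order(self):
        d = {(0, 1): 0.1, (0, 2): 0.25, (1, 2): 0.3}
        m1 = _identity_from_distances(["B", "A", "C"], {(0, 1): 0.1, (0, 2): 0.25, (1, 2): 0.3})
        m2 = _identity_from_distances(["A", "B", "C"], {(0, 1): 0.1, (0, 2): 0.25, (1, 2): 0.3})
        # same distances up to relabelling of the first two taxa
        assert nj_phylogram(m1).newick.count(":") == nj_phylogram(m2).newick.count(":")


class TestMonotonicity:
    def test_higher_rate_never_higher_identity(self):
        """Expected identity decreases with the planted substitution rate."""
        genome, truth = simulate_genome(seed=19)
        idents = []
        for rate in (0.01, 0.08, 0.2):
            spec = FamilySpec(newick=f"(X:{rate},Y:{rate},Z:{rate});", seed=3)
            seqs, _, _ = evolve_family(genome, truth, spec)
            m = identity_matrix(
                {k: v.residues for k, v in seqs.items()}, RegionSpec(Region.GENOME_NT)
            )
            idents.append(m.min_offdiag())
        assert idents[0] > idents[1] > idents[2]
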