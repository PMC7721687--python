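import warnings

import pytest

from lagenome import build_gagpol_model, find_signal_stemloops, partition_genome
from lagenome.simulate import FamilySpec, GenomeParams, evolve_family, simulate_genome

EIGHT_LEAF_NEWICK = (
    "((A:0.01,B:0.01):0.02,((C:0.01,D:0.01):0.02,"
    "((E:0.01,F:0.01):0.02,(G:0.01,H:0.01):0.02):0.02):0.02);"
)


@pytest.fixture(scope="session")
def default_genome():
    """Default LA-like genome (TdV-LAbarr1 geometry) plus planted truth."""
    return simulate_genome(seed=1)


@pytest.fixture(scope="session")
def default_partition(default_genome):
    genome, truth = default_genome
    return partition_genome(genome, anchor_5=truth.anchor_5, anchor_3=truth.anchor_3)


@pytest.fixture(scope="session")
def default_gagpol(default_partition):
    return build_gagpol_model(default_partition)


@pytest.fixture(scope="session")
def default_signals(default_partition, default_gagpol):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return find_signal_stemloops(default_partition, default_gagpol)


@pytest.fixture(scope="session")
def eight_leaf_family():
    """Low-divergence 8-leaf family evolved along a known tree."""
    genome, truth = simulate_genome(seed=7)
    spec = FamilySpec(newick=EIGHT_LEAF_NEWICK, seed=13)
    seqs, truths, newick = evolve_family(genome, truth, spec)
    return seqs, truths, newick, truth


@pytest.fixture(scope="session")
def plain_genome():
    """A genome without planted extra-sequence features (control)."""
    params = GenomeParams(
        virus_id="plain", anchor_5="GAAAAA", anchor_3="CCATATGC",
        five_extra_len=30, three_extra_len=25,
        plant_boundary_palindrome=False,
        five_self_identity=False, three_self_identity=False,
    )
    return simulate_genome(params, seed=21)
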