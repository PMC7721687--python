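"""Evolve a genome family along a known tree and compare it back.

Generates five descendants of one LA-like genome (two tight clades plus a
distant outgroup), computes the Gag-Pol percent-identity matrix, and
rebuilds the phylogeny by neighbor joining on d = 1 - identity/100.
"""

import numpy as np

from lagenome import (
    Region,
    RegionSpec,
    build_gagpol_model,
    identity_matrix,
    nj_phylogram,
    partition_genome,
)
from lagenome.simulate import FamilySpec, evolve_family, simulate_genome

genome, truth = simulate_genome(seed=11)
spec = FamilySpec(
    newick="((A:0.005,B:0.005):0.08,(C:0.005,D:0.005):0.08,E:0.25);", seed=2
)
seqs, truths, true_tree = evolve_family(genome, truth, spec)

fusions = {}
for name, vs in sorted(seqs.items()):
    part = partition_genome(vs, anchor_5=truth.anchor_5, anchor_3=truth.anchor_3)
    fusions[name] = build_gagpol_model(part).fusion_protein

m = identity_matrix(fusions, RegionSpec(Region.GAGPOL_AA))
print("Gag-Pol percent-identity matrix:")
print(np.round(m.values, 1))
# Within-clade pairs (A-B, C-D) sit far above between-clade pairs, and the
# outgroup E is lowest, mirroring the planted divergence strata.

tree = nj_phylogram(m)
print("NJ phylogram:", tree.newick)
print("true tree:   ", true_tree)
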