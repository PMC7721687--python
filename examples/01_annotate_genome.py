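"""Simulate an LA-like genome and annotate it end to end.

Builds a 4,622-nt synthetic genome with the TdV-LAbarr1 geometry, splits
it into 5'-extra / canonical / 3'-extra zones, and annotates Gag, the -1
frameshift site, Pol and the Gag-Pol fusion protein.
"""

from lagenome import build_gagpol_model, partition_genome, to_paper_coord
from lagenome.simulate import simulate_genome

genome, truth = simulate_genome(seed=1)
part = partition_genome(genome, anchor_5="AATTAA", anchor_3="CCATAAGC")
print(f"{genome.id}: {genome.length} nt")
print(f"zones: 5'extra {part.five_extra_len} / canonical {part.canonical_len}"
      f" / 3'extra {part.three_extra_len}")
print(f"first base is {to_paper_coord(part, 1)} in the signed convention")

gp = build_gagpol_model(part)
print(f"Gag ORF: canonical {gp.gag.start}-{gp.gag.end} ({len(gp.gag.protein)} aa)")
print(f"slippery heptamer {gp.slippery.heptamer} at canonical {gp.slippery.position}")
print(f"Pol ORF: canonical {gp.pol.start}-{gp.pol.end} in frame {gp.pol.frame}"
      f" (= gag frame {gp.gag.frame} shifted by -1)")
print(f"Gag-Pol fusion: {len(gp.fusion_protein)} aa; putative re-initiation"
      f" ATGs at {list(gp.reinit_codons)}")
# The fusion length is the biologically relevant output: Gag read up to the
# heptamer, then the -1 frame through the whole polymerase.
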