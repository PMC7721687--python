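"""Characterise the 5'/3' extra sequences of a synthetic genome.

Finds the planted self-identity stretches (extra-zone windows repeated in
the canonical interior), scans the boundary region for near-palindromes,
and locates a host rRNA-like fragment carried by a second genome's 5'
extra sequence.
"""

from lagenome import (
    Zone,
    ViralSequence,
    find_self_identity,
    match_host_sequences,
    palindrome_scan,
    partition_genome,
)
from lagenome.simulate import preset, simulate_genome

genome, truth = simulate_genome(seed=1)
part = partition_genome(genome, anchor_5="AATTAA", anchor_3="CCATAAGC")

print("self-identity (extra zone vs canonical interior):")
for m in find_self_identity(part):
    print(f"  {m.length} nt, 100% identity: {m.paper_string(part)}")
# The 51-nt top match straddles the 5' boundary, like the published one.

print("near-palindromes around the 5' boundary:")
for h in palindrome_scan(part.sequence.residues[:40], min_arm=4, max_loop=8):
    print(f"  span {h.start}-{h.end}, arms {h.arm_len} nt, loop {h.loop_len},"
          f" {h.mismatches} mismatches")

lus4, lus4_truth = simulate_genome(preset("lalus4"), seed=3)
part4 = partition_genome(lus4, anchor_5="GAAAAA", anchor_3="CCATATGC")
host = ViralSequence(id=lus4_truth.host_fragment["host_id"],
                     residues=lus4_truth.host_fragment["host_residues"])
print(f"host-like content of {lus4.id}'s 187-nt 5' extra:")
for h in match_host_sequences(part4, Zone.FIVE_EXTRA, [host]):
    print(f"  {h.length} nt of {h.identity}% identity to {h.host_id} ({h.strand})")
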