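"""Fold the published 5'-boundary stem loop and form its kissing complex.

The 31-mer printed for the TdV-LAbarr1 5' boundary folds into a hairpin
whose unpaired loop carries the first four canonical bases (AAUU); the
homologous copy inside the canonical zone exposes the complementary loop,
and the two can anneal into a 4-bp kissing complex.
"""

from lagenome import fold_hairpin, kissing_pairs

BOUNDARY_31MER = "CACGTAGCTTTATTAATTAATATGCTACGTG"

hp = fold_hairpin(BOUNDARY_31MER)
print(BOUNDARY_31MER.replace("T", "U"))
print(hp.dot_bracket())
print(f"dG = {hp.dG_kcal:.2f} kcal/mol = {hp.dG_kJ:.1f} kJ/mol"
      f" ({hp.n_stem_pairs} stem pairs, loop {hp.loop_seq})")
# Around -50 kJ/mol: a stable terminal structure that could shield the
# ssRNA end from exonucleases.

kc = kissing_pairs(hp.loop_seq, hp.loop_seq)
print(f"kissing complex between the two homologous loops: {kc.n_pairs} bp"
      f" (5'-{kc.loop_a}/3'-{kc.loop_b[::-1]})")
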