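# Nearest-neighbor helix stack free energies, kcal/mol, 37 C, 1 M NaCl
# (Turner 2004 RNA set; Watson-Crick and GU wobble pairs).
# Row = outer pair (5' base, 3' base) at (i, j); column = inner pair at (i+1, j-1).
pair	CG	GC	GU	UG	AU	UA
CG	-3.30	-2.40	-1.40	-2.10	-2.10	-2.10
GC	-3.40	-3.30	-1.50	-2.50	-2.40	-2.20
GU	-2.50	-2.10	-0.50	1.30	-1.30	-1.40
UG	-1.50	-1.40	0.30	-0.50	-1.00	-0.60
AU	-2.20	-2.10	-0.60	-1.40	-0.90	-1.10
UA	-2.40	-2.10	-1.00	-1.30	-1.30	-0.90
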