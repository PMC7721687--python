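# Hairpin-loop terminal mismatch free energies, kcal/mol, 37 C (Turner 2004 RNA set).
# Row = closing pair (i, j) plus the first loop base 3' of i; column = first loop base 5' of j.
pair	x	A	C	G	U
CG	A	-1.50	-1.50	-1.40	-1.50
CG	C	-1.00	-1.10	-1.00	-0.80
CG	G	-2.30	-1.50	-2.40	-1.50
CG	U	-1.00	-1.40	-1.00	-2.10
GC	A	-1.10	-1.50	-1.30	-1.50
GC	C	-1.10	-0.70	-1.10	-0.50
GC	G	-2.50	-1.50	-2.20	-1.50
GC	U	-1.10	-1.00	-1.10	-1.60
GU	A	0.20	-0.50	-0.30	-0.50
GU	C	-0.10	-0.20	-0.10	-0.20
GU	G	-1.00	-0.50	-1.10	-0.50
GU	U	-0.10	-0.30	-0.10	-1.00
UG	A	-0.50	-0.30	-0.60	-0.30
UG	C	-0.20	-0.10	-0.20	0.00
UG	G	-0.90	-0.30	-1.10	-0.30
UG	U	-0.20	-0.10	-0.20	-0.90
AU	A	-0.30	-0.50	-0.30	-0.50
AU	C	-0.10	-0.20	-0.10	-0.20
AU	G	-1.20	-0.50	-1.10	-0.50
AU	U	-0.10	-0.30	-0.10	-1.20
UA	A	-0.50	-0.30	-0.50	-0.30
UA	C	-0.20	-0.10	-0.20	0.00
UA	G	-1.50	-0.30	-1.50	-0.30
UA	U	-0.20	-0.10	-0.20	-0.90
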