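# Methods

This note records the models, parameter choices and known limitations
behind `lagenome`. It documents what the code computes; every number shown
by the README or examples is produced by running the code.

## Genome model and coordinates

An LA helper-virus cDNA is modelled as three zones: a 5'-extra sequence, a
canonical genome and a 3'-extra sequence. The canonical zone is anchored at
the conserved 5' motif (`GAAAAA` in ScV-LA viruses; the homologous `AATTAA`
in TdV-LAbarr1) and ends at the 3' terminus of the conserved 3' octamer
(`CCATATGC`-style). When several anchor occurrences exist, the one that
maximises canonical length while keeping the extra zone within a 400-nt cap
is chosen — extras observed so far are ≤ 252 nt, so the cap is generous
without letting an interior motif copy masquerade as the genome start. A
homology mode projects zone boundaries from an annotated reference through
a global alignment instead and takes precedence when both are available;
this is how a novel genome whose canonical zone is defined only by homology
is handled.

Internally all coordinates are 0-based half-open. The signed convention
(canonical 1..N; (−)k upstream; (+)k downstream) is purely presentational;
`to_paper_coord`/`from_paper_coord` are exact inverses and
`span_length` counts closed intervals across zone boundaries, so a span
like (−)14..37 is 51 nt.

## ORFs and the −1 frameshift

ORFs are ATG-initiated and stop-terminated, one per (frame, stop codon),
reading from the first ATG after the previous stop; `end` excludes the
stop codon, so `end − start + 1 = 3 × protein length` always holds (the
published ORF spans for these genomes are not multiples of three, so their
stop convention is ambiguous; ours is chosen for testability). Gag is the
5'-most ORF of Gag-like size (default ≥ 400 residues; LA Gag is ~680 aa,
so the threshold discards spurious ORFs without risking the real one).

Slippery sites match `XXXYYYZ` with, by default, Y ∈ {A, U} and Z ≠ G —
the canonical −1 PRF pattern that covers `GGGUUUA` — and a relaxed mode
scans the bare pattern. The site chosen for the model is the one nearest
to, and upstream of, the Gag stop. The Gag-Pol fusion is spliced at
residue level: Gag codons ending at or before the heptamer's last base,
then translation resuming one nucleotide 5' of the next Gag codon
boundary (the −1 frame), through to the Pol stop. Pol itself is the
longest ORF in frame (gag − 1) mod 3 overlapping or following the site.

Re-initiation codons are the in-frame ATGs strictly after the Gag stop and
5' of the Pol catalytic domain, operationalised as the first third of the
Pol ORF. This includes Pol's own start ATG deliberately: Pol is normally
expressed only within the fusion, so every in-frame ATG between the Gag
stop and the catalytic domain — the ORF start included — is a candidate
re-initiation codon. (Defining them as "ATGs before the Pol start" would
make the set structurally empty, since any such ATG would itself begin the
longest ORF.)

## Hairpin thermodynamics

Every cis signal of these genomes is a simple stem loop, so folding is
restricted to nested single-hairpin structures: one helix, interrupted by
bulges and internal loops of at most 30 unpaired nucleotides (mirroring
the MFOLD settings used for these genomes), closed by a hairpin loop of at
least 3 nt. No multiloops, no pseudoknots, no partition function.

Free energies are the published Turner 2004 nearest-neighbor RNA
parameters at 37 °C (1 M NaCl), shipped as TSV files: helix stacks
(Watson-Crick + GU), loop-size initiation penalties, hairpin terminal
mismatches, the 0.5 kcal/mol terminal-AU/GU helix-end penalty, and a
0.6 kcal/mol·nt Ninio asymmetry term capped at 3.0. Two deliberate
simplifications: (i) hairpin loops of size ≥ 4 get their first-mismatch
stacking term — this is part of the standard model and without it every
hairpin is systematically ~1.2 kcal/mol too weak; (ii) interior and bulge
loops carry neither mismatch bonuses nor AU-closure penalties, which are
of similar magnitude and opposite sign, so omitting both keeps the model
simple at little cost. Tetraloop/triloop bonuses and dangling ends are not
modelled. Energies are computed in kcal/mol and converted to kJ/mol by the
exact factor 4.184, because the literature on these genomes prints kJ/mol.
On the printed 5'-boundary 31-mer this model gives −12.10 kcal/mol
(−50.6 kJ/mol), against −50 kJ/mol from MFOLD 3 and −11.5 kcal/mol from a
full Turner 2004 implementation — differences within the ±10% band used
wherever printed energies are reproduced.

The minimum-free-energy structure is found by an exact dynamic programme
over closing pairs; suboptimal enumeration (default: within 5% of the MFE,
at most 50 structures, matching the MFOLD suboptimality settings) prunes
with the same tables. Ties break to the smaller span, then 5'-most. The
contract for both is fixed by an exhaustive structure enumeration that the
test suite runs on every random sequence up to 22 nt.

## Signal discovery

Five signal kinds are annotated on the canonical zone: the 5' conserved
motif (within canonical 1–10); the most AU-rich 15-nt window of the 5' UTR
(the underline-only published boundary makes the max-AU window the natural
operationalisation; ties go 5'-most); the frameshift stimulatory hairpin,
the best fold starting within 12 nt 3' of the heptamer; the ~24-nt
packaging hairpin, the best 20–30-nt-span hairpin in the 3' half of the
canonical zone — ranked by loop-sequence identity to a reference packaging
loop when one is supplied, because the loop, not the stem, is the
conserved determinant, and by ΔG otherwise; and the replication hairpin,
the best fold wholly within the last 40 canonical nt. Genome-scale scans
slide 44-nt windows in 15-nt steps and cap interior loops at 12 nt — a
speed bound only; MFE stem loops at these sizes essentially never use
larger interior loops.

## Extra-sequence analysis

Self-identity and shared stretches are maximal exact matches of at least
13 nt (the shortest stretch reported for these genomes). Query windows
include 60 nt of adjacent canonical sequence because the published 51-nt
self-identity straddles the zone boundary; query and subject intervals
must be disjoint. The implementation seeds on 13-mers and extends, but its
contract is the quadratic brute-force oracle in the tests. Near-palindromes
are arm pairs (≥ 8 nt by default) in reverse complement around a loop of
≤ 8 nt with ≤ 2 substitutions; arms never end on a mismatch, and hits
contained in another hit are suppressed. Arms are substitution-only:
bulged "almost palindromes" are the folding module's job, which is why the
published 31-mer (whose stem carries a 2×1 interior loop) is reported as a
stem loop at full span but as a shorter core by the palindrome scanner.
Host search is Smith-Waterman (match +5, mismatch −4, gap 10/0.5) on both
strands; the raw local alignment over-extends past a high-identity block
into flanking noise, so hits are trimmed to the maximal-scoring column
segment under a +1/−identity-odds scheme (Kadane), which reports blocks
the way the field states them ("178 nt of 100% identity").

## Comparative analysis

Percent identity is identical columns over non-gap-pair columns of a
single global pairwise alignment (nucleotide +5/−4, protein BLOSUM62, both
with gap open 10 and extend 0.5), rounded to one decimal. Pairwise
alignments rather than one MSA drive the matrices, keeping every entry
independent of input order; published matrices built with ClustalW/MUSCLE
are reproduced to within ±1.5 percentage points. Regions are projected
onto each genome through an alignment to an annotated reference; the RdRp
conserved region is operationalised as the central third of Pol by residue
count, and the 19-aa variable region as the stretch immediately downstream
of the cap-snatching His-154. Trees are neighbor joining (scikit-bio) on
d = 1 − identity/100 with labels sorted first for determinism and negative
branch lengths clamped to zero with a warning; the three-taxon closed form
and planted-topology recovery (Robinson-Foulds 0) pin its behavior in the
tests.

## Synthetic data

The generator emits genomes with the full LA architecture. Defaults follow
the TdV-LAbarr1 geometry: 14 + 4,591 + 17 nt, `AATTAA`/`CCATAAGC` anchors,
Gag from canonical 61 (677 aa), heptamer `GGGTTTA` at 1,981, Pol at
2,376–4,550 in the −1 frame, an all-AU 15-mer at 40–54, the published
31-mer planted across the 5' boundary, a 51-nt self-identity copy planted
inside Gag at canonical 400 (on a codon boundary, where the 31-mer is
stop-free), a 16-nt 3' self-identity copy, a 24-nt packaging hairpin at
4,205 and a 15-nt replication hairpin at 4,560. Presets mirror the other
sequenced geometries (`la1`: 252/4,580/42; `lalus4`: 187/4,580/9 with a
178-nt host rRNA-like fragment in the 5' extra). Planted hairpin stems are
GC-only with A/C loops: they contain no T, hence cannot harbour stop
codons in any frame, and their folding recovery is unambiguous.

Construction writes fixed feature blocks, fills free positions uniformly
at random, mirrors tied positions (the self-identity copies), then runs a
deterministic repair pass that removes chance stop codons from the Gag and
fusion frames, spurious ATGs from the re-initiation window, and spurious
slippery heptamers from Gag, and enforces mismatch guards at the flanks of
planted exact matches so they are exactly maximal. Rare unresolvable
collisions trigger a new sub-seeded attempt, so output is still a pure
function of the seed. Flanking sequence can still contribute a few extra
base pairs to a planted hairpin's MFE structure, so recovered
frameshift/replication spans may slightly exceed the designed stems; tests
assert containment, and exact span recovery where guards make it possible
(the packaging signal).

Families evolve along a user-supplied Newick guide tree under
Jukes-Cantor: each unprotected site substitutes with probability
¾(1 − e^(−4t/3)) per branch of length t expected substitutions/site.
Substitution draws that would break the coding architecture (a stop in
Gag or the fusion frame, a new ATG in the re-initiation window) take a
different base or are skipped — the same purifying constraint real LA
genomes are under. Optional indels (per-site rate, geometric lengths) are
confined to non-coding, unprotected regions, and all truth coordinates are
remapped through them. Feature protection (on by default) masks planted
signals from mutation so per-leaf truth stays exact.

What the generator does not emulate: sequencing error and coverage
variation, real codon usage and GC content (filler is uniform), selection
heterogeneity along branches, recombination, and the unknown true origin
of the extra sequences. Passing tests therefore demonstrate correctness
of the algorithms under the planted architecture, not robustness to every
property of field isolates.

## Problem sizes and determinism

The test suite runs entirely on synthetic data: one default genome, an
8-leaf family at ≤ 0.05 substitutions/site for topology recovery, and
oracle equivalence on sequences ≤ 24 nt (folding) and windows ≤ a few
hundred nt (matching) — sizes at which the brute-force oracles are exact
and fast. All simulations are seeded; re-running the pipeline with the
same inputs yields byte-identical JSON/TSV/GFF3/Newick artifacts.
Reproduction of accession-dependent published values (identity
percentages, the 51-nt self-identity, the −59 kJ/mol frameshift hairpin)
requires the GenBank records under `data/accessions/`, fetched explicitly
with `scripts/fetch_accessions.py`; without them those checks fail with a
pointer to the fetch script rather than silently passing.

## Known limitations

* The folding model is hairpin-only; genome-wide MFE folding, multiloops
  and pseudoknots are out of scope, and kissing complexes are detected
  combinatorially (best contiguous duplex), not thermodynamically.
* Identity to printed matrices carries the declared ±1.5-point aligner
  tolerance; the exact programs behind the published values differ.
* The palindrome scanner does not model bulged arms.
* Published coordinate inconsistencies in the source material (a 22-nt
  stretch printed with a 23-nt span; packaging-loop changes listed 5' of
  the packaging stem loop's stated position) are left as-is: the scanners
  search the whole region and force no agreement.
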