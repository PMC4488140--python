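# Methods

This note records the models and procedures ssrkit implements, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic fixtures do and do not establish about real data.

## Repeat scanning

The scanner reports maximal perfect tracts of primitive 2–6 bp motifs.
For each period *p* the positions where `seq[i] == seq[i+p]` (both
unambiguous) form match runs; a run covering region `[i, j+p)` contributes
`floor((j+p−i)/p)` complete units anchored at the run start, truncating
any trailing partial unit. A region is reported iff the unit count reaches
the period's minimum (6/5/5/4/4 for p = 2…6) and its leading *p* bases are
a primitive motif. Because a lower-period tract observed at a multiple of
its true period always has a non-primitive leading unit, this enforces the
smallest-period rule without any cross-period bookkeeping: an AT×8 tract
is never additionally reported as ATAT×4. Conventions:

* Mononucleotide runs are not searched; the attribute scheme starts at
  dinucleotides.
* N breaks a tract; tracts never span N, and ambiguity codes other than N
  are coerced to N at ingest (count logged).
* Same-motif abutting tracts are one run by construction; zero-gap
  neighbours of *different* motifs merge into compound loci. Compound
  events count once in dataset totals and are also tallied separately;
  their member motifs contribute individually to motif/period tables.
  Both the event tally and the member tally are reported, since either
  reading of "SSRs present in compound formation" is defensible.
* Internally all coordinates are 0-based half-open; GFF3 and marker
  tables serialize 1-based inclusive.

The motif family representative is the lexicographic minimum over the
motif's cyclic rotations and those of its reverse complement. Exhaustive
enumeration gives 4/10/33/102/350 families for periods 2–6, which the test
suite checks.

## Classification

* Length classes split at 20 bp with tracts of exactly 20 bp in Class I
  ("longer/shorter than 20 bp" leaves the boundary open; ≥ 20 matches the
  common Class I definition).
* Composition is decided by the motif's A+T fraction: above ½ AT-rich,
  below ½ GC-rich, exactly ½ balanced. Because a perfect tract is the
  motif repeated, motif and tract composition coincide.
* Integer percentages round half away from zero — the only rule
  consistent with every printed percentage in the source tables
  (e.g. 528/1850 = 28.54% printed as 29%).
* The overall column is the unweighted arithmetic mean of the per-dataset
  integer percentages, not a pooled-count percentage: pooled counts give
  71% dinucleotide where the published overall is 64%, which only the
  unweighted mean reproduces. Overall density uses the same mean over the
  per-dataset kbp/SSR values.
* The published EST density (6) disagrees with its own printed counts
  (41 Mbp / 7479 ≈ 5.5 → 5); the per-dataset EST density is therefore not
  used as a reproduction target, while the genome/GSS densities and the
  overall mean (computed from the printed row) are.

## Primer design

Design is a deterministic simplified stand-in for a primer3 run, chosen so
that outputs are exactly reproducible and every constraint is explicit:

| parameter | default | note |
|---|---|---|
| flank length | 200 bp each side | truncated at sequence ends, flag recorded |
| primer length | 18–24 bp | all windows enumerated |
| Tm | 55–60 °C | Wallace rule 2(A+T)+4(G+C); matches the annealing range |
| GC | 40–60% | |
| product | 100–400 bp | 5′-to-5′ span, tract strictly inside |

Score is the summed deviation of both primer Tms from the Tm-range
midpoint (57.5 °C); ties break to the smaller product, then the leftmost
forward, then the leftmost reverse window. Failures are data, not errors:
`insufficient_flank` when a flank is shorter than the minimum primer
length, `no_compliant_pair` when no window combination satisfies all
constraints.

Redundancy is exact pair-level sequence identity after orientation
normalization (a forward/reverse swap is the same pair); the first
occurrence in input order is kept. The criterion of the original
redundancy filter is not public; sequence identity is the most
conservative reading and is applied in two stages — within each dataset,
then across the pooled set.

## Electronic PCR

A binding site is a semi-global alignment of the primer against either
strand. Budgets are per primer: at most 3 mismatches and 2 gaps (counted
per inserted/deleted base), and the 3′-terminal 2 bases must match exactly
with no gaps — the anchor reflects polymerase extension chemistry and is
an addition to the published budget description, configurable and on by
default. Alignment semantics: all alignments with cost ≤ max_mm +
2·max_gaps (cost = mismatches + 2·gaps) are candidates; overlapping
candidates collapse to the minimum-cost one (ties: fewer gaps, then
leftmost); the budgets are then judged on the surviving alignment. This
makes a site whose best explanation is four substitutions fail, even
though a contrived 3-mismatch/2-gap alignment of it exists.

The search is a layered dynamic program vectorized over genome positions
(layer g = minimum mismatches with ≤ g gaps), so a genome is processed
with O(primer length × gap budget) numpy passes; zero-budget searches use
plain substring scanning. Amplicons are convergent, non-overlapping site
pairs on one sequence within 5 kb, sized 5′-to-5′; both orientations are
searched and identical spans reported once.

Physical mapping calls a marker unique/multi/none by its genome-wide
amplicon count; compound-SSR markers are excluded from transferability, as
are multi- and no-hit markers. A cross-taxon amplicon is polymorphic when
its size differs from the marker's expected product by ≥ 10 bp (the
comparison is against the expected size, not pairwise among taxa).
Transferability of a genome is the fraction of markers with ≥ 1 amplicon.

## TE, miRNA and functional association

The TE screen translates the flanked region (left flank + tract + right
flank) in six frames and aligns each frame locally against a TE protein
library with BLOSUM62, gap open 11 / extend 1. A hit requires ≥ 65%
identity over the aligned region and a Karlin–Altschul E-value ≤ 1e-10
computed with the standard ungapped BLOSUM62 parameters (λ = 0.3176,
K = 0.134) over frame length × total library residues. Full BLAST
heuristics (seeding, HSP chaining) are intentionally not reproduced: the
thresholds define the association and the exhaustive local alignment is
strictly more sensitive. The TE family is read from the library header's
Class/Family token (e.g. `LTR/Copia`).

The miRNA screen slides each mature sequence (18–26 nt, both orientations)
ungapped along the flanked region and keeps offsets with ≤ 4 mismatches —
at this length and mismatch ceiling a gapped search adds nothing. The
200 bp/side flank used for the TE screen is reused here.

Candidate precursors are validated with a base-pair-maximization fold
(Watson–Crick plus G:U wobble, minimum loop 3) in place of thermodynamic
minimum-free-energy folding: a window is a valid hairpin iff ≥ 55% of its
bases pair and a single stem-loop contains ≥ 60% of the mature-site bases
in paired positions. The two thresholds are toolkit choices, configurable,
and not taken from any published protocol; the pairing count itself is
checked against an independent cubic-time recursion in the tests.

Functional categorization is a case-insensitive keyword map over
externally supplied annotation strings into hypothetical/uncharacterized,
stress-related, transcription factor, housekeeping, other, or
non-functional when no annotation exists; keyword lists are configurable
and matched in that priority order.

## Marker statistics

Allele calls are codominant allele sizes pooled across accessions. PIC
uses the Botstein definition (the simpler 1 − Σpᵢ² is available by
switch). The cohort mean alleles/locus is truncated, not rounded, to two
decimals — 1047 alleles over 243 polymorphic loci is 4.3086 and is
reported as 4.30, matching how the source cohort prints it. Allele totals
and the PIC range are reported over polymorphic markers. A marker is
"transferable" in the wet-lab sense when it amplifies in at least two
accessions (the table does not identify the source accession).

The five pre-selection criteria apply in order: unique reference hit →
transferable to ≥ 1 taxon → in-silico polymorphic → not TE-associated;
the fifth (functional priority) is a sort key, not a filter. Attrition is
reported per criterion.

## Synthetic fixtures

The generator emulates the study's inputs at desk scale: i.i.d. background
at GC 0.39 (Musa-like), optionally redrawn until repeat-free; planted SSR
tracts across all periods and both length classes; TE fragments
reverse-translated (one fixed codon per residue) from library proteins
planted 30 bp from dedicated SSRs; perfect inverted-repeat hairpins with
the mature site in the 5′ arm planted 40 bp from others. One guard base on
each side of a planted tract is set so the repeat cannot extend into the
background, making the truth-table coordinates exactly the maximal tract.
The default whole-pipeline fixture is a 1 Mbp genome with 200 SSRs, 10 TE
fragments and 10 hairpins; a single seed governs all randomness.

What passing on fixtures does **not** show: real genomes have
non-uniform base composition, interrupted and nested repeats, genuine TE
copy-number structure and thermodynamically constrained hairpins, none of
which the i.i.d. generator models. Fixture results validate the
algorithms' contracts (exactness, budgets, monotonicity), not the
biological frequencies of any species; the published genome-scale counts
require the real assemblies and are out of scope here.

Divergence for transferability experiments applies per-base substitutions
(uniform over the three alternatives) and optional geometric-length
indels (mean 2). Genotype tables are diploid i.i.d. draws from specified
allele-frequency vectors.

## Problem sizes and numerical choices

The acceptance script and test suite run planted-truth at 1 Mbp/200 SSRs,
scanner-oracle equivalence on 200 sequences ≤ 2 kb, transferability on a
50 kb/20-marker panel across substitution rates 0/0.05/0.30 with replicate
seeds, and hairpin-oracle checks on 50 windows ≤ 200 nt — sizes chosen so
each suite establishes its property with comfortable margins on a single
CPU. Degenerate inputs are contracts, not crashes: zero loci report an
absent density rather than infinity, empty observation sets for
polymorphism raise, design failures carry reasons. All randomness flows
from explicit seeds; identical seeds give byte-identical outputs.

## Known limitations

* Primer design ignores secondary structure, dimers and nearest-neighbor
  thermodynamics (a config switch reserves room for the latter).
* The E-value approximation uses ungapped statistics for a gapped
  alignment, which is conservative at these thresholds but not identical
  to BLASTX reporting.
* The hairpin validity thresholds are heuristics; a thermodynamic folder
  would be stricter.
* EST cleanup reduces quality/low-complexity trimming to terminal
  homopolymer and N-run removal (tail ≥ 8 bp, keep ≥ 100 bp), since the
  original trimmer's parameters are unpublished; both are configurable.
* Compound-SSR markers get primers but are excluded from transferability,
  mirroring the published protocol.
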