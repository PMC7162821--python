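# Methods

This note documents the models and procedures implemented in
`hugephage`, the parameters that matter, the numerical choices behind
them, and what the synthetic-data tests do and do not demonstrate.

## Scope and data model

The package analyses assembled contigs, not reads. Its inputs are
FASTA sequences, per-gene annotation tables (best database hit per gene:
taxon lineage from domain to genus, a functional keyword, a bitscore)
standing in for UniProt/ggKbase-style searches, and protein similarity
edge tables standing in for all-vs-all (MMseqs-style) and
profile–profile (HHblits-style) searches. Read assembly, read-mapping
curation, and the upstream homology searches themselves are out of
scope; their outputs are consumed through documented TSV schemas.
Coordinates are 0-based half-open internally and 1-based inclusive in
GFF3 output.

## Assembly QC

**Circularization.** A linear representation of a circular genome ends
with an exact copy of its beginning. `detect_circularity` returns the
longest exact prefix–suffix overlap within [50 bp, 20 kb] (both bounds
configurable; defaults chosen since overlaps shorter than ~50 bp arise
by chance and assembler overlaps rarely exceed tens of kb). A hit marks
the contig potentially complete.

**Repeats.** Repeat search is exact-match, seeded by k-mer anchors
(k = 31 for the >5 kb concatemer screen, k = 13 for the >25 bp
tabulation; an anchor must fit inside the smallest reported repeat) and
extended along matching diagonals to maximality. The test suite asserts
exact equivalence with a quadratic all-diagonals scan, for direct and
for inverted (reverse-complement) repeats. A contig that is k ≥ 2
near-perfect (≥ 99% identity) tandem copies of a unit is flagged a
concatemer artifact with corrected length equal to the unit; long
repeats that do not form whole-contig tandem copies set a manual-review
flag instead. Corrected sequences are retained for analysis when the
corrected length is at least 200 kb — the huge-phage size floor — and
the retention rule is exposed as a parameter (`keep_min_bp`) rather
than hard-wired.

**GC skew.** Windowed skew (G−C)/(G+C) (window 1 kb, step 500 bp;
windows without G or C score 0) and the cumulative per-window (G−C)
curve. Under bidirectional replication the cumulative curve is
piecewise linear with opposite slopes meeting at origin and terminus;
under unidirectional replication it is a single trend. Classification
fits continuous piecewise-linear models with 0, 1 or 2 breakpoints by
least squares (coarse grid, then local refinement). "Bidirectional"
requires alternating slope signs, fit R² ≥ 0.85 and per-segment
equivalent skew amplitude ≥ 0.02 (half the generator's default planted
amplitude; the amplitude floor rejects the drift a random walk shows,
which otherwise passes the R² test surprisingly often).
"Unidirectional" requires the same of the single-slope fit. Because the
least-squares breakpoint trades position against global slope and is
noisy to several kb, accepted breakpoints are snapped to the local
extremum of the cumulative curve (the falling-to-rising inflection — the
cumulative minimum — is the origin), which localizes the inflection to
a window or two. Profiles with fewer than 10 windows are not
classified. Reorientation removes the terminal overlap and rotates a
circular genome to start at the intergenic gap nearest the inferred
origin; rotation is exactly invertible.

## Gene calling and alternative genetic codes

The ORF caller is deliberately minimal and fully specified, so coding
density is a reproducible statistic rather than an artifact of an
external predictor's heuristics: maximal ORFs on both strands that
start at the first in-frame ATG/GTG/TTG after a stop and end at a stop
codon of the active code, minimum 60 codons (configurable; short enough
to keep density high on real gene layouts, long enough to suppress
random open frames). Overlapping calls are resolved greedily by length,
ties by leftmost start then plus strand. Coding density is the fraction
of positions covered by at least one call.

Genetic codes are expressed as stop-codon reassignments of the standard
bacterial table 11: `TAG_recoded` (amber → Gln, the reassignment
observed in human/animal-associated huge phages), `TGA_recoded`
(opal → Trp) and a single-stop `code6_like` (TAA/TAG → Gln). A genome
is flagged when its code-11 density falls below 0.78 — the regime in
which published huge-phage genomes turned out to use alternative codes —
and candidate codes are then tried. A candidate is adopted only if its
density exceeds the code-11 density by more than 0.10 (the margin
prevents reassignment on noise), and candidates with a single remaining
stop codon are rejected when they fuse genes implausibly: 95th-percentile
gene length more than 3× the code-11 value, or more than 20% of calls
each spanning ≥ 3 code-11 genes. The thresholds quantify "unlikely
gene-fusion predictions", which published practice left qualitative.

## Element classification

Per-rank taxonomy votes count each gene's best hit once; a rank's
winner needs strictly more than 50% of that rank's voting genes (genes
without a call abstain and leave the denominator; ranks are evaluated
independently and all are reported). Phage markers and plasmid genes
are matched case-insensitively against an editable lexicon
(`data/markers.tsv`), since annotation keyword dialects vary. The
hypothetical fraction counts genes lacking a functional keyword over
all genes, treating genes absent from the hit table as hypothetical.

Prophage detection looks for the transition into a bacterial flank: a
terminal region ≥ 20 kb in which ≥ 70% of hit-bearing genes are
confident bacterial predictions (non-hypothetical keyword, bitscore
≥ 60, bacterial domain) and such genes cover ≥ 50% of the flank's
bases, while confident genes cover ≤ 40% of the two windows just inside
the boundary. The interior test is deliberately local (the remainder of
the contig would include the opposite flank) and coverage-based (the
phage interior has sparser, weaker hits, so per-base coverage separates
the regions far more sharply than per-hit-gene fractions). Among
qualifying boundaries the one with the largest flank-vs-interior
contrast is reported per end.

The rules fire in order: prophage transition → prophage_containing;
plasmid partitioning/conjugation genes without phage markers →
plasmid_like; phage markers, a user placement override (standing in for
phylogenetic placement of markerless candidates, which is out of
scope), or no domain-level winner with hypothetical fraction ≥ 0.6 →
phage; else unknown. Contigs under 200 kb are rejected unless they
carry a CRISPR array. Every decision carries a rule trace.

## CRISPR arrays, spacer matching, interaction network

Array detection is CRT/MinCED-style: exact 8-mers recurring at a period
compatible with one repeat (19–48 bp) plus one spacer (17–72 bp) seed a
candidate; the repeat is extended while the two seed copies agree, then
further copies are collected in both directions allowing one mismatch
per copy, always taking the nearest admissible occurrence (two periods
can fit in the spacer window, so preferring a farther copy would
silently skip one). Because a two-copy seed can be offset by a chance
flanking match, detection iterates walk → gap-fill → boundary
refinement to a fixed point: walking matches on the repeat's core (up
to two columns shaved per end) so boundary noise cannot consume the
mismatch budget, gaps wide enough for a missed copy are searched and
filled, and boundaries are reset to the longest run of columns on which
≥ 90% of copies agree (treated as a correction of at most four columns
per side, so a genuinely degenerate interior column cannot re-segment
the repeat), extended by unanimous flanking columns. Arrays need ≥ 3
repeat copies; consensus is per-column majority; orientation is
reported as unknown (repeat-degeneracy orientation calling is not
implemented). Planted-array recovery is ≥ 95% across repeat lengths
21–45 bp and 4–10 spacers, with boundaries within ±2 bp, and the
false-positive rate on random sequence is below 0.05 arrays per Mb.

Spacer matching is an ungapped Hamming scan of both strands, made exact
and fast by the pigeonhole principle (a window within m mismatches must
contain one of m+1 exact spacer pieces; candidates from piece lookups
are verified directly). The alignment length is the full spacer length;
the strict tier keeps alignments > 24 bp with ≤ 1 mismatch, and for
every (array, target) pair with a strict hit the array's spacers are
rescanned against that target sequence at ≤ 3 mismatches (the expanded
tier). Restricting the expansion to the already-matched target sequence
follows the stated search procedure; expanding to a whole sample would
change the tier semantics. An array's trivial self-matches (its own
spacers inside its own span) are suppressed. The interaction network
collapses matches per (array-owner, target) pair into directed edges
carrying strict/expanded counts: solid with ≥ 1 strict match, dashed
otherwise; self-targeting edges are flagged. Consensus repeats of phage
and host arrays are compared by ungapped sliding alignment in both
orientations over at least half the shorter repeat.

## Host prediction

Phylum votes over a phage's gene hits (one vote per gene, best hit;
genes without a phylum call excluded from the denominator) assign a
host only when the top phylum has at least 3× the runner-up's count —
the boundary is inclusive (3.0× passes), since the published wording
does not resolve equality, and a single voted phylum trivially passes.
CRISPR evidence takes the phylum of bacterial contigs whose arrays
strictly target the phage; multiple implicated phyla are recorded as a
conflict. Reconciliation: agreement fixes the host; one evidence line
gives a tentative call; conflict leaves the host unassigned. On
planted communities the two lines never disagree, matching the complete
vote/CRISPR agreement reported for real huge phages.

## Protein families

Step one filters the all-vs-all edge table at E ≤ 1e-3 and coverage
≥ 0.5 and runs greedy set cover: the node covering the most uncovered
nodes (itself plus neighbours) becomes a representative and claims
them; ties break to the lexicographically smallest id, making the
result independent of input order. Step two keeps profile edges with
probability ≥ 95% and coverage ≥ 0.50, weights them probability/100 ×
coverage, and runs Markov clustering with inflation 2.0. All
subfamilies enter the MCL graph, singletons included. Numerical
choices the algorithm name alone does not fix: self-loops weighted with
each node's maximum incident weight (1 for isolated nodes), pruning of
entries below 1e-5, convergence tolerance 1e-6, iteration cap 100,
attractor overlap resolved by larger mass then lower index — the
canonical MCL formulation. Columns remain stochastic to 1e-9 after
every normalization (asserted in tests), and clusters on ≤ 12-node
graphs equal an independently coded reference implementation. Families
are unions of co-clustered subfamilies and always partition the input
proteins; a subfamily appearing in two clusters is a hard error.

## Summary statistics

The genome-size report gives 100 kb histogram bins, the median size,
and Spearman's ρ between tRNA count and genome length with a seeded
permutation p-value (10,000 permutations, two-sided). Permutation
rather than asymptotic p-values because desk-scale n is small.
Correlation on fewer than 3 rows or constant input is reported as
undefined rather than computed.

## The synthetic-community generator

Genomes are concatenations of synthetic genes — random-codon ORFs with
log-normal length (median ≈ 300 codons, σ = 0.45, clipped to
60–2500 codons), 20% on the minus strand, separated by 20–150 bp
intergenic gaps — giving coding densities around 0.87–0.91, comfortably
above the 0.78 flag. Codon sampling excludes the active code's stop
codons, with the letter-level GC adjusted by fixed-point iteration so
the realized GC stays within 2 points of target despite the exclusion
of AT-rich stops. Skew is planted at the letter level (default
amplitude 0.05): G-excess on one replichore and C-excess on the other
for bidirectional genomes (default breakpoints at 25% and 75% of the
unit), uniform G-excess for unidirectional. TAG-recoded genomes use TAG
as a sense codon internally and terminate genes with TAA/TGA, which
drives their code-11 density to ~0.6. Planted features (arrays,
protospacers, terminal repeats) are allocated through a collision map so
they never overwrite each other, and concatemerization/terminal-overlap
transforms are applied last with truth coordinates shifted into every
copy. Annotation tables sample per-gene hits from configurable
domain/phylum fractions (defaults give phages a 4:1 host-phylum ratio,
a 0.70 hypothetical fraction and a split domain profile; hosts a
dominant own-phylum bacterial profile), with marker/plasmid keywords
assigned to designated genes. A single integer seed drives one RNG;
sub-generators draw in fixed order, so identical specs are
byte-identical.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sequencing error and assembly
chimeras other than clean tandem concatemers; genuine protein evolution
(annotation lineages are sampled labels, not homology); degenerate
repeat copies inside CRISPR arrays; codon-usage structure beyond
letter frequencies; gene overlap and operon structure; coverage trends,
which real curation combines with GC skew. Performance numbers from
planted communities are upper bounds on real-data performance.

## Problem sizes in the standard checks

The standard recovery community is 10 phages (200–700 kb, one tandem
dimer, one prophage with 40 kb flanks, one TAG-recoded genome, half
circularized with 120 bp terminal repeats) and 5 hosts (250–350 kb)
whose arrays target the phages with 0–3 mismatch spacers — about 5 Mb
of sequence. Genetic-code accuracy is measured on 50 genomes of 30 kb
per truth code; oracle-equivalence checks run on ≥ 100 seeded instances
of 1.5–15 kb; the tRNA correlation uses n = 200 genomes with a planted
rank correlation of 0.6. These sizes keep a full run in minutes while
leaving every decision threshold exercised at its boundary.

## Known limitations

* The ORF caller does not refine translation-initiation sites or use
  ribosome-binding signals; density comparisons between codes are
  internally consistent but absolute densities differ from Prodigal's.
* Spacer matching is ungapped by design; a protospacer with an indel
  will be missed (short-alignment BLAST would find some of these).
* Array orientation and Cas-gene subtyping are not called; a Cas
  annotation table can be joined for reporting only.
* Phylogenetic placement (terminase/capsid trees), whole-genome
  clustering, and vContact2-style corroboration are out of scope; the
  placement-tree rescue of markerless phage candidates is replaced by
  an explicit override flag.
* Only TAG/TGA readthrough codes are searched by default; other
  stop-codon repurposings are configurable but not enumerated.
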