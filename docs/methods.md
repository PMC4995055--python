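# Methods

`mitokit` implements the standard comparative analysis performed on a newly
sequenced insect mitochondrial genome — the kind of ~15 kb circular molecule
carrying 13 protein-coding genes (PCGs), ~21–22 tRNAs, two rRNAs and one
large non-coding control region (CR).  The package's worked example is the
citrus spiny whitefly (*Aleurocanthus spiniferus*) mitogenome, whose
published annotation table ships as a fixture; everything else runs on
user-supplied GenBank/TSV/FASTA inputs or on synthetic genomes the package
generates itself.

## Annotation model

Coordinates are 1-based inclusive throughout (the GenBank convention);
0-based half-open conversions exist only at I/O edges.  A feature with
`end < start` wraps the origin of a circular molecule and has length
`(L − start + 1) + end`.  Junction spacers are evaluated in the table's
listing order, not genomic-position order, because published IGN
(intergenic-nucleotide) columns follow listing order: the spacer printed on
row *i* is `start(i+1) − end(i) − 1`, and a circular annotation contributes
one extra wrap spacer (last row back to the first).  Negative spacers are
gene overlaps.

Every column of an annotation table exists in two forms: *declared* (what
the annotators printed) and *computed* (derived from coordinates or
sequence).  Published tables are not always internally consistent — the
packaged whitefly table disagrees with its own coordinates in four places
(the trnF overlap, the nad1 spacer, the CR size, the wrap spacer) — so
`validate_declared` reports every mismatch and the toolkit never silently
corrects either side.  Summary reports accept a `source` switch; the
declared source reproduces the published totals (51 bp of overlap over 10
gene pairs, 91 bp of IGN over 14 pairs for the fixture).

## Composition and strand skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C), computed on the
strand as given; both are antisymmetric under reverse complement (a
property-tested invariant).  Ambiguity codes are excluded from every
denominator and counted separately.  `skews_from_percentages` applies the
same formulas to printed percentages, for reproducing published skew values
without the sequence.  Reporting precision follows field convention —
percentages to one decimal, skews to three — while internal values keep
full precision.  Column statistics over annotation tables (e.g. the mean
tRNA A+T content) are unweighted means of the declared column.

## Codon usage

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: ATA = Met, TGA = Trp, AGA/AGG = Ser), the code insect
mitogenomes use; the table id is a parameter everywhere.  Mitochondrial CDS
may end on an incomplete stop codon (a trailing T or TA completed to TAA by
post-transcriptional polyadenylation), so a CDS of length 3k+1 ending in T
or 3k+2 ending in TA is classified as incomplete-stop; a 3k CDS must end in
a stop codon.  Codon-usage statistics trim incomplete tails and exclude
terminal stop codons.  RSCU(c) = count(c) / mean count over c's synonymous
family; family sums therefore equal family sizes whenever the family is
observed, and unobserved families report 0 (not NaN) for table stability.

## Ka/Ks (NG86 with Jukes–Cantor correction)

Synonymous/nonsynonymous site counts per codon enumerate the three
single-nucleotide mutations at each position; mutations creating stop
codons are excluded from the denominator.  Observed differences between two
codons are averaged over all minimal mutational paths with uniform weights;
paths through stop codons are excluded with renormalization (if every path
is blocked — possible only in degenerate cases — all paths are used).
S and N are averaged over the two sequences; pS = Sd/S and pN = Nd/N are
corrected with d = −(3/4)·ln(1 − (4/3)p), undefined for p ≥ 3/4
(saturation, flagged).  Panel means over a species set are unweighted means
of the defined pairwise values over all unordered pairs; pairs with
undefined correction are excluded rather than clamped, to avoid bias from
saturated pairs, and their count is reported.  Ka/Ks > 1 is classified as
positive selection, < 1 purifying, = 1 neutral.

No maximum-likelihood codon-model estimation is provided, and inputs must
be pre-aligned (equal length after codon-aware trimming); alignment
construction is out of scope.

## Gene orders and rearrangements

A gene order is a signed circular permutation.  Adjacencies are unordered
pairs of gene extremities (head/tail), which makes the representation
invariant under rotation and whole-molecule reversal — a circular genome
has no distinguished start or strand.  The breakpoint distance between two
orders on a common gene set (orders are restricted to their shared alphabet
first, with removals reported, since whitefly mitogenomes lose tRNAs) is
the number of adjacencies of one order absent from the other.

`describe_events` decomposes the query into maximal runs of genes occupying
consecutive reference positions.  A run extends while the sign relationship
(query sign × reference sign) stays constant and the walk is one of:
forward unflipped, backward with flipped signs (a proper inversion), or
backward with unflipped signs (order reversal without strand change — the
form the whitefly *nad3-trnG-cox3* cluster takes).  Runs are labelled
inverted when walked backward (or, for single genes, when the sign is
flipped) and translocated when their unsigned neighbours differ between
query and reference.  For scrambles composed of one or two inversions,
block boundaries coincide exactly with signed breakpoints; three or more
nested inversions can create an unflipped reversal that legitimately merges
across a breakpoint, so the count-equality property is only guaranteed in
the former regime.

The shipped `ancestral-insect` reference is the canonical ancestral insect
(*Drosophila yakuba*-type) gene order, written with the same leucine-tRNA
labels as the whitefly fixture; any reference can be supplied as a one-line
text file.  The distance tree is neighbor joining (negative branches
clamped to zero) on the pairwise breakpoint matrix — an explicit stand-in
for rearrangement-count tree search: it orders taxa by breakpoint distance
and does not infer ancestral gene orders or event counts.

## Control-region dissection

Four element classes are detected and tiled into a non-overlapping ordered
report:

* **Tandem repeats** — a deliberately simple seed-and-extend detector:
  exact k-mer self-matches (k = 8 or the period, whichever is smaller) seed
  candidate periods; arrays extend copy by copy with banded edit-distance
  alignment (edlib), each copy accepted while its identity to the first
  copy is ≥ `min_identity` (default 0.8) with at most
  `max_indels_per_copy` indels (default 8), which accommodates internally
  deleted copies.  Fractional trailing copies are counted when at least
  3 nt of the unit prefix match exactly.  Overlapping candidates are
  resolved longest-span-first (ties: leftmost, then smaller period) —
  deterministic, and a long array can never be truncated by a short
  overlapping candidate.  Single-base units are skipped; homopolymer runs
  are their own element class.  This is not a reimplementation of any
  external repeat finder's alignment-weight scoring; per-copy identity
  against the seed copy is the only score.  Detection may start a few
  bases before a planted array when the flank coincidentally matches the
  unit's tail (a rotated phase of the same array), so recovered start
  positions are exact only up to such rotations.
* **Stem-loops** — all (arm1, loop, arm2) placements with the loop length
  in range, arms reverse-complementary with at most `max_mismatches`
  interior mismatches (G·U counts as pairing by default, as in tRNA
  stems), innermost and outermost pairs required to pair, and maximality
  enforced both outward (the flanking pair does not pair) and inward (the
  stem cannot grow without shrinking the loop below its minimum).  The
  scanner is verified against an exhaustive placement oracle on short
  sequences.  Repeat arrays routinely contain incidental cross-copy
  complementarity, so `hairpins_outside_repeats` discards hairpins inside
  repeat arrays before classification.
* **Homopolymer runs** — maximal runs of one base above a length cutoff
  (poly-T runs are the replication-associated element of insect CRs).
* **Partition** — detector hits claim intervals with precedence
  repeat-array > stem-loop > poly-T; remaining intervals are classified
  `gc-elevated` when their windowed mean G+C fraction exceeds
  `gc_threshold` (default 0.35, midway between an AT-rich genome
  background of ~0.29 and the elevated ~0.39 segments these CRs carry),
  else `spacer`.  Segments tile the sequence exactly; any overlap after
  precedence resolution is an internal error.

## Synthetic genomes

The generator is the ground-truth oracle for every stage.  The default
spec mirrors the whitefly-like architecture: 36 genes plus CR in the
rearranged whitefly order with the fixture's strands, lengths, start/stop
codons and anticodons, laid head-to-tail (zero spacers, total 15,170 bp),
with coding-strand composition targets A/T/G/C = 0.310/0.398/0.168/0.124.
One printed gene size (nad3, 353 bp) is incompatible with its printed
incomplete-T stop (353 mod 3 = 2), so the generator plants an incomplete
TA stop there.

Composition targets apply to each gene's coding strand; reverse-strand
genes are planted as reverse complements, producing genome-strand
asymmetry as in real mixed-strand mitogenomes (an all-forward switch
exists for composition-recovery tests).  PCG codons are drawn from a
sense-codon distribution whose marginal base composition equals the target
exactly (a fixed-point adjustment; naive i.i.d. sampling with stop
rejection under-represents A, because stop codons are A-rich).

The CR is assembled to a five-part plan: a 293 bp GC-0.39 segment, a 69 bp
poly-T run, a 44 bp hairpin (16 bp stem, 12 nt loop), a 19 bp pad, two
exact 128 bp tandem copies, a 94 bp intervening spacer, three 38 bp copies
with a 6 bp internal deletion in the third, and a 37 bp tail pad (920 bp
total).  Structural segments use exact-count base sampling and a few
boundary constraints (the GC segment does not end in T, the hairpin arm
does not start with T, loop ends and pad boundaries do not pair), so the
planted plan is recovered by the detectors for *every* seed, not just
favourable ones.  Intervening spacers and pads are deliberately GC-poor
(G+C = 0.10) so the composition classes separate deterministically; real
whitefly CR spacers can be GC-richer than the genome, a feature the
generator does not emulate.  Everything is byte-deterministic under a
fixed seed.

`evolve_cds` provides event-count ground truth for Ka/Ks: single-nucleotide
changes are proposed (uniform position, uniform non-stop alternative) and
accepted with relative probability 1 (synonymous) versus ω (nonsynonymous),
both rescaled by max(1, ω) so ω > 1 keeps the intended ratio; realized
synonymous/nonsynonymous event counts are returned.  The proposal scheme
matches the NG86 site definition (stop-excluded denominators), so the NG86
estimator recovers the planted ω without systematic bias; recovery
experiments use 10,000 codons at 0.3 substitutions per codon, where the
estimate lands within a few percent of the planted value while staying far
from Jukes–Cantor saturation.  `scramble_order` applies logged random
inversions/translocations to gene orders.

What passing on synthetic data does *not* show: real mitogenomes have
sequencing error, composition heterogeneity along the molecule, diverged
(not exact-copy) repeat units, selection heterogeneity across sites, and
annotation errors — none of which the generator emulates.  The
table-driven analytics, by contrast, are exercised on the real published
whitefly annotation.

## Numerical and degenerate-input conventions

Zero denominators yield explicit `None`/flag values, never NaN: skews of
AT- or GC-free sequences, Ka/Ks with Ks = 0 (flagged `Ks-zero`, or
`zero-over-zero` for identical sequences), Jukes–Cantor at p ≥ 3/4.
Codon-rank ties break lexicographically.  Empty inputs (tables, sequences,
subsets) raise errors naming the offending row or gene.  All randomness is
numpy `default_rng` seeded explicitly; identical seeds give identical
bytes.

## Known limitations

tRNA secondary structure, rRNA structure modelling, thermodynamic folding
of stem-loops, Hannenhalli–Pevzner/DCJ rearrangement distances, and
likelihood phylogenetics are all out of scope.  The repeat finder is a
detector for well-formed arrays, not a general repeat annotator; heavily
diverged arrays (identity below ~0.8) fall below its default thresholds.
The rearrangement block labels are a local, greedy description, not a
parsimonious event reconstruction.
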