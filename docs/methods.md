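# Methods

## Overview

`olcorrect` inserts a supervised classification step between the
overlapping and contigging stages of an overlap-layout-consensus assembler.
Candidate overlaps are detected by shared-k-mer seeding and alignment, each
candidate is described by alignment, k-mer-frequency and
comparative-genomics features, a classifier trained on labeled overlaps
predicts each candidate true or false, predicted-false overlaps are removed,
and a minimal unitigger assembles the remainder. All stages operate on
synthetic data with known ground truth, so every claim of the method is
testable end to end.

## Overlap detection

Candidates are found by indexing canonical k-mers (seed k = 14 by default;
only every 8th position of a read is indexed while every position is
queried, so any shared exact stretch of ≥ 21 bp produces a seed). Each
seed-implied offset is evaluated by a unit-cost alignment of the implied
overlapping substrings (via edlib), with the floating end free. A candidate
is kept when the overlap spans at least `min_overlap = 30` alignment columns
at a disagreement rate (mismatches + gap bases over columns) of at most
`max_error = 0.06` — the conventional hash-overlap operating point. Among
competing alignments of one pair/orientation the highest-scoring one
(matches − mismatches − gap bases; ties to the smaller |a_hang|, then fewer
gap events) is kept. Hang conventions are AMOS-style: `a_hang` is the
oriented readB start relative to readA, `b_hang` the readB end past readA's
end; flipped overlaps refer to the reverse complement of readB; pairs are
canonicalized with the lexicographically smaller id first. On ≤ 30
error-free reads the candidate set equals an exhaustive all-pairs,
all-offsets dynamic-programming oracle (tested).

The 6% disagreement rate counts mismatches plus gap *bases*; "disagreement"
is not usually decomposed further in overlapper conventions, and counting
gap events instead would only loosen the filter slightly at these error
rates.

## Features

**Alignment features** — mismatch fraction (mismatches / overlap columns),
percent identity (matches / overlap columns), overlap length, mismatch
count, gap-event count.

**K-mer features** (default k = 16, configurable to 17) — all canonical
k-mers of the read set are counted once; a k-mer's *normalized frequency* is
its count divided by the expected sequencing coverage, so unique genome
sequence sits near 1 and an n-copy repeat near n. For each candidate, the
k-mers of *both* reads' overlap substrings are pooled (duplicates included —
this makes the statistic symmetric under swapping the reads) and the
25th/50th/75th-percentile normalized frequencies are reported using the
nearest-rank (lower) convention, which is deterministic and
interpolation-free. Also reported: the fraction of k-mers whose normalized
frequency exceeds 1.5 × the model-wide mean over distinct k-mers (a
per-overlap mean would make the threshold self-referential), and the number
of k-mers with raw count exactly 1 (likely sequencing errors). Expected
coverage defaults to total read bases over a genome-size estimate (the
number of distinct canonical k-mers if no better estimate is given) and is
user-overridable; the pipeline passes the configured simulation coverage.

**Comparative score** — both reads are mapped to each genome of a related
panel with a seed-and-extend mapper (16-mer seeds, minimum identity 0.80,
minimum read coverage 0.80, both strands; overlapping seed groups merged;
hits occupying the same interval deduplicated to the best). Every (hitA,
hitB) combination within one genome is classified *overlapping* when the
strand relationship matches the candidate's orientation and the implied
relative offset matches the candidate's `a_hang` within a 30 bp tolerance
(absorbing indel drift), else *non-overlapping*; its score is the sum of the
two hits' matching bases. With `max s_ovl` and `max s_nonovl` the best
scores of each class over the whole panel, the final feature is
`+log2(max s_ovl − max s_nonovl + 1)` when the overlapping side wins,
`−log2(max s_nonovl − max s_ovl + 1)` when it loses, `0` on a tie. The
negative sign on the second branch is required for the feature to
discriminate at all: a read pair whose best placements disagree must score
below one whose best placements co-locate. When a genome yields only one
class of combination the other maximum is taken as 0 (no support). The
score is *missing* — a distinct marker, never 0, because 0 means "tie" —
when either read maps nowhere in the panel.

## Ground truth

A candidate is labeled true when the two reads' error-free source intervals
lie on the same genome, intersect by at least 30 bp (the overlapper's
minimum — a shorter genomic intersection could not support a detectable
overlap), and have a strand relationship consistent with the candidate's
orientation. Inverted-repeat alignments between co-located reads on
inconsistent strands are therefore false: they are not usable assembly
overlaps.

## Classification

Four algorithms, all behind one interface: an entropy-split decision tree
(minimum leaf size 2), a 100-tree random forest, and naive Bayes with
per-class normal densities or per-class kernel density estimates
(normal-reference bandwidth, densities evaluated on a 512-point grid from at
most 3000 training samples per class/feature for speed). Missing feature
values are first-class: the tree and forest use scikit-learn's native
missing-value routing (missing samples follow the branch that scored better
in training), and the naive Bayes variants omit the missing feature's
likelihood term. Missing is never imputed as 0. Class imbalance is left as
it occurs in the data. Support-vector machines are deliberately absent.

Metrics follow the standard conventions for this problem: *positive* means
predicted true overlap; accuracy is the fraction of correct predictions,
the false positive rate divides false positives by the actual false
overlaps, the false negative rate divides false negatives by the actual
true overlaps.

The end-to-end pipeline defaults to the random forest. On the standard
benchmark the single tree and the forest have similar accuracy, but the
forest's bagging smooths the decision boundary in the noisy
repeat-boundary region of feature space, and measured across benchmark
seeds it removes surviving false overlaps more consistently — which is what
the downstream assembly comparison is sensitive to. The single tree remains
the reference for the classification-transfer checks.

## Assembly

The contigger is a deliberately conservative unitigger. Contained reads are
set aside; dovetail edges get an absolute per-component layout (strand and
offset by breadth-first propagation; edges whose strand implication
conflicts with the assignment — typically repeat-induced — are dropped);
transitive edges are removed with a 10 bp slack for indel drift; contigs
are maximal simple paths of nodes with unique in/out edges, and any branch
node terminates paths and joins none itself. This conservatism is the
mechanism by which false overlaps damage an assembly: every surviving
repeat-induced edge leaves a branch that fragments contigs.

The pipeline additionally requires *overlap confirmation* in both the
corrected and the uncorrected control assembly: an edge is kept only if some
third read overlaps both its endpoints at geometrically consistent offsets
(a confirming triangle), iterated to a fixpoint. True overlaps at ordinary
coverage are densely cross-confirmed; an isolated spurious edge — e.g. a
rare repeat-induced overlap left behind after classification has removed
its companions — loses its triangle and is dropped, while the dense
uncorrected repeat tangle confirms itself and keeps its branches. The rule
is symmetric between the two arms; it differentiates them only through
edge density.

Consensus is computed by splicing reads along each path: each read's
junction with the growing contig is located by aligning the contig's
overlap-spanning suffix inside the read, and the read's extension is
appended. A rigid per-column majority vote was implemented first and
rejected: with indel errors every read's bases shift off the column grid
past its first indel, and the measured consensus error (~12% at the default
0.3% indel rate) collapsed reference coverage. Splice consensus keeps every
consensus base anchored to one read, so contig accuracy equals single-read
accuracy (~98.7% at default error rates), comfortably above the 95%
identity used in evaluation. The cost is that consensus does not average
out substitution errors; a polishing pass would, but is out of scope.

Evaluation: N50 is reference-relative (shortest contig length at which all
contigs that long or longer sum to ≥ half the reference length; 0 if never
reached). Percent genome matched aligns each contig in ~1 kb pieces to the
reference (both strands, ≥ 95% identity, ≥ 100 bp) and reports the fraction
of reference positions covered at least once. A contig whose piece
alignments are non-colinear (offset deviation > 1 kb or strand flip) is
flagged as a potential misassembly.

## Synthetic data

`SimConfig` defaults define the standard benchmark: a 200 kb uniform-random
genome carrying one 1.5 kb × 6-copy repeat family at 1% per-copy divergence
and one 400 bp × 10-copy exact family (repeat-dense enough to induce
thousands of false overlaps, small enough for minutes-scale runs); related
genomes derived at 8% and 9% divergence (≈ 92/91% identity, matching the
identity range of usable related strains); 10× coverage of 400 ± 40 bp
reads with 1% substitution and 0.3% length-1 indel errors (shotgun-like
error rates; error-type structure beyond mismatch/gap counts is not
modeled, because no feature uses it). The background genome composition is
uniform over A/C/G/T so repeats are the only homology source. Reads are
sampled uniformly from both strands; minus-strand placements store the
forward-genome interval and the read stores the reverse complement. All
outputs are pure functions of configuration and seed.

What the simulator does **not** emulate: real base-composition bias,
homopolymer-specific 454 errors, quality values, paired ends, and
chromosome-scale repeat structure. Passing tests on this generator show
that the method behaves as designed when repeats are the only confounder;
they do not bound its accuracy on real sequencing data.

The benchmark experiment simulates two *independent* genomes (train/test
share no sequence, verified by k-mer intersection), mirroring the
train-on-one-organism, assemble-another design.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open throughout.
- Canonical k-mers are the lexicographic minimum of a k-mer and its reverse
  complement; k-mers containing N are skipped; k ≤ 31 (2-bit packing).
- Alignment statistics come from unit-cost edit-distance alignments with
  extended CIGARs; `overlap_length` is the alignment column count, so
  mismatch fraction remains well-defined with gaps.
- Quartiles use the nearest-rank (lower) convention.
- Empty overlap tables, empty prediction sets and classifiers asked to
  predict on empty tables are all legal and return empty results; training
  on a single-class label set is an error.
- N50 of an empty or insufficient contig set is 0, never undefined.
- Model files carry a magic string and version; loading anything else is an
  error, not a misprediction.

## Known limitations

- The comparative score's max-over-combinations is noisy when a repeat
  family's copies are near-identical and reads lie entirely inside a copy:
  the margin between the best overlapping and best non-overlapping
  combination shrinks toward sampling noise of the panel divergence, which
  bounds per-pair classification accuracy in repeat interiors.
- Splice consensus propagates single-read errors into contigs (no error
  averaging).
- The unitigger performs no repeat resolution beyond overlap filtering: no
  scaffolding, no bubble popping, no paired-end information.
- Read mapping aligns whole reads (no split alignments), so hits spanning a
  repeat/flank junction report a blended identity.
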