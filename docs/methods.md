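# Methods

## Model and assumptions

`tfcoop` treats cooperative TF binding as a statistical co-occurrence
problem: if two factors work together at short range, their binding
sites should appear within a bounded center-to-center distance in the
same promoters more often than their individual site densities predict.
The unit of evidence is the site *pair*, and all probabilities live on
the space of observed pairs, not of sequence positions.  The method
makes no use of strand orientation, spacing preferences inside the
allowed window, or motif families; it assumes site predictions are
noisy (false-positive rich) and pushes the cleanup into three places:
the importance filter, the average product correction (APC), and the
shuffled-set background.

## Site prediction

Windows on both strands are scored as log₂-odds of the PWM against a
per-sequence mononucleotide background.  Background frequencies are
computed over non-N positions, floored at 0.01 and renormalized — the
floor keeps log-odds finite on extreme compositions, and the
per-sequence choice makes scores robust on GC-skewed promoters without
needing a genome-wide model.  Raw scores are min-max normalized onto
[0, 1] over the matrix's attainable range *on the scanned strand*;
per-strand ranges make the score of a site exactly invariant under
reverse complementation of the input.  A window's normalized score is
therefore "how close to this matrix's best attainable match", which is
what a fractional threshold should mean; the default 0.85 is a
stand-in for published stringent profile cut-offs and is configurable
per matrix and per run.  Windows containing N are unmatchable rather
than guessed.  If a matrix's attainable range is numerically empty
(degenerate matrix equal to the background) the sequence yields no
sites for it.

Parsed count matrices get an additive pseudocount of 0.01 per cell
before row normalization, which keeps every log-odds finite.  Note this
is an *absolute* pseudocount: a matrix supplied as probabilities (rows
summing to 1) is shifted by up to ~1%, while large-total count
encodings are essentially unaffected, so count encodings are preferred
for interchange.

## The six scoring phases

1. **Matrix construction and column filter.**  Sites are tallied into
   the sequence × motif count matrix.  Columns whose totals fall outside
   the closed [5%, 95%] quantile interval of nonzero column totals are
   dropped (zero columns always are).  The quantile rule is scale-free:
   it adapts to any library size and site-density regime rather than
   fixing absolute count cut-offs.
2. **Importance filter.**  A motif is important *for a sequence* iff
   its sequence/motif PMI is strictly positive, i.e. it is enriched in
   that sequence relative to its corpus-wide rate.  Cells with zero
   counts are never evaluated.  This is a knife-edge test for motifs
   distributed perfectly evenly (PMI ≈ 0), which is visible on planted
   benchmarks: a motif inserted exactly once per sequence survives in
   roughly the sequences with below-average total site load.
3. **Overlap resolution.**  Same-motif sites whose intervals overlap
   (chained transitively) collapse to the one whose center is nearest
   the TSS; ties go to the smaller start, then the '+' strand.  The TSS
   index defaults to 500, matching −500..+100 promoter windows
   (and the center of the 1000 bp synthetic sequences).
4. **Pair formation.**  Unordered within-sequence site pairs with
   center distance in the closed interval [5, 20] bp.  Homotypic pairs
   (a motif with itself) are excluded by default — reported
   cooperations are heterotypic — behind a switch.
5. **Weighted cumulative PMI.**  Probabilities are per-sequence: the
   joint is the pair's share of the sequence's N_s pair occurrences and
   a motif's marginal is its share of the 2·N_s pair ends, so joint and
   marginals live on one sample space.  Sequence weights w_s = N_s/ΣN_s
   make the corpus-level score a pair-count-weighted average; a
   corpus-pooled probability mode is available behind
   `probability_scope="corpus"`, but with pooled probabilities the
   weighted sum degenerates to a single term, so per-sequence is the
   default.
6. **APC and significance.**  The corrected score subtracts
   mean_a·mean_b/overall_mean, where means run over *observed* pairs
   only (unobserved pairs are non-entries, not zeros).  An exactly zero
   overall mean leaves the correction undefined and raises.  Corrected
   scores are z-transformed with the sample (n−1) standard deviation
   over all scored pairs — not only positive ones — and z ≥ 3 marks
   significance.  A zero-spread distribution yields no significant
   pairs (with a warning) rather than an error.

## Background correction and the α scale

Backgrounds are l independent k-let-preserving shuffles of the input
set (default k = 3: mono-, di- and trinucleotide counts — and hence
site cores — are conserved).  The shuffler draws a uniform random
arborescence toward the trail's end vertex on the (k−1)-mer de Bruijn
multigraph with Wilson's loop-erased random walk, fixes those edges as
last exits, permutes the remaining exits uniformly, and walks the
Euler trail — the classic Altschul–Erikson construction generalized to
k-lets, unbiased among admissible arrangements and linear-time in
practice.  N is an ordinary fifth symbol, so N-containing k-mers are
conserved, never invented.  Substreams are keyed by (root seed, set
index, sequence id), making backgrounds reproducible and independent
of processing order.

The full pipeline (scan through APC, no significance cut) runs on every
background set with the foreground configuration.  Per pair, the
background average divides by the *full* l — a pair absent from a set
contributes 0, since the average is over a fixed-length sample — and a
Monte-Carlo standard error accompanies each average.  The default
l = 1000 follows the "sufficiently many sets" reasoning of the
background model; the test profile uses l = 50, where the Monte-Carlo
error of the averages is already small against the foreground scores
(the stability test doubles l and checks averages move < 3 standard
errors).  Background values are APC-corrected scores; a flag
(`background_use_apc=False`) switches to uncorrected pair scores, as
the two conventions are both defensible.

Classification only touches significant pairs: the background never
alters significance, it only splits significant pairs into
sequence-set **specific** (PMI_specific > 0, strictly) and **common**
(≤ 0, boundary included).  α ∈ [−1, 1] linearly scales the subtracted
background, (1 + α)·AVG; −1 recovers the uncorrected output bitwise
and +1 is the upper bound, beyond which the background's role would be
overestimated.  Missing background estimates for a significant pair
count as 0 with a logged warning.

## Synthetic benchmark generator

The generator emulates a planted-pair simulation: 200 promoters of
1000 bp with i.i.d. bases (uniform by default; a GC-skew option exists
for composition-robustness checks), each carrying one consensus pair of
two planted motifs at a center-to-center spacing uniform on [5, 20] bp,
in random left/right order and strand, overwriting the background so
lengths stay exact.  The truth table records every planted interval and
the realized spacing.

Design choices worth stating:

- **Planted motifs are width 5.**  With center spacing down to 5 bp,
  planted blocks can only stay disjoint — and the planted consensus
  strings only remain verbatim in the sequence, which is what the truth
  table promises — if (w_A + w_B)/2 ≤ 5.
- **Consensus planting, not PWM sampling:** the planted signal is the
  matrices' consensus strings, so the scanner's score-1.0 calls are the
  ground truth.
- **Decoy library (default 20 matrices).**  Columns are Dirichlet with
  concentration `sharpness` (default 1000, i.e. near-consensus
  matching, like stringent profile cut-offs) on a random preferred
  base.  The first two decoys take the shortest width of the range
  (default widths 4–12): every real matrix library contains short,
  degenerate, hit-dense profiles, and those columns populate the upper
  tail of the column-total spectrum — without them the planted columns
  would be the most extreme totals of the whole library and the
  phase-1 quantile filter would remove the signal itself, which is not
  how a planted pair sits inside a realistic library.  Decoys whose
  consensus contains a planted consensus (either strand) are redrawn,
  keeping the benchmark's ground truth unambiguous; partially
  overlapping matches remain, and do occasionally produce the known
  satellite effect of extra "artificial" pairs at the planted loci.
- `insertions_per_sequence=0` produces pure background sets for null
  calibration.

What the generator does **not** emulate: real promoter base
composition and repeat structure, clustered/homotypic site
architecture, correlated motif families within the library, and any
biological coupling between sequences.  Passing the planted-recovery
test therefore shows the pipeline detects an arrangement-specific
co-occurrence signal against realistic site-density noise — not that
it ranks biological cooperations correctly in real promoters.

## Numerical choices

- Score comparisons at the site threshold use a 1e-9 tolerance so a
  consensus window passes a threshold of exactly 1.0.
- Quantiles use linear interpolation (numpy default); the filter
  interval is closed on both ends.
- Stable sorts and lexicographic pair keys everywhere; overlap ties
  break by (distance to TSS, start, strand).
- z-scores use ddof = 1; a single scored pair or zero spread yields no
  significant pairs.
- All RNG flows from `numpy.random.SeedSequence`; shuffle substreams
  hash (seed, set index, CRC32 of the sequence id).

## Problem sizes used in the shipped protocols

The test suite and `scripts/acceptance.py` run the planted benchmark at
its native 200 × 1000 bp size with 50 background sets, 20 replicates
for the recovery rate, and a 20-seed unplanted null; the smaller
80 × 500 bp configuration with 12 decoys serves as the worked example
and fixture.  These sizes were chosen so a full protocol completes in
minutes on a single core while the recovery statistics remain stable.

## Known limitations

- The scanner is not a reimplementation of any proprietary matcher;
  absolute site counts depend on the open normalization chosen here,
  so published absolute pair counts obtained with proprietary scanners
  are not bit-reproducible.
- The importance filter's strict-positivity rule is knife-edged for
  perfectly evenly distributed motifs (see above).
- No multiple-testing control beyond the z ≥ 3 cut and no per-pair
  permutation p-values; α is swept manually (start around 0.2), not
  selected automatically.
- Distance is the only pairing constraint; orientation and exact
  spacing preferences are out of scope.
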