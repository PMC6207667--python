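# Methods

## Coordinate model and file formats

All coordinates are 0-based half-open (BED convention). Peaks are
narrowPeak intervals carrying a signal (column 7) and a summit offset
(column 10); a summit of −1 is mapped to the interval midpoint
(floor), because every summit-anchored window downstream needs a
concrete point. Genes are consumed as BED6-like TSV (chrom, start,
end, id, score, strand) — only TSS, TTS and strand are used, so a
GFF3 converter is deliberately out of scope. Signal tracks use
bedGraph step semantics with uncovered bases implicitly zero.

## Peak-set comparison

* **Reciprocal overlap** follows `bedtools intersect -f f -r`: two
  intervals overlap at fraction *f* when the shared bases cover ≥ *f*
  of *both* lengths (≥ is inclusive, so two 100-bp intervals sharing
  exactly 50 bp pass at *f* = 0.5).
* **Shared-peak matrix**: for each pair of datasets the smaller set is
  the denominator; a cell is the percentage of its peaks with ≥1
  reciprocal partner in the other set. A zero-peak dataset yields a
  missing cell (the ratio is undefined), not 0.
* **Consensus and classification** use plain ≥1-bp overlap: peaks of
  one clade are merged into consensus regions; the union of the two
  clade consensus sets is merged again and each region labeled
  `shared` when both clades contribute, else `A_only`/`B_only`. The
  reciprocal-*f* rule applies only to the pairwise matrix, the
  blacklist, and sub-clade analysis; occupancy-style consensus uses
  single-base overlap.
* **Sub-clade-specific peaks** must reciprocally overlap a peak of at
  least one *other* member of the same sub-clade and touch no peak
  (≥1 bp) outside it. A singleton sub-clade waives the co-member
  requirement (its unique peaks qualify), mirroring how a TF that
  forms a clade by itself must be handled.
* **Blacklist**: a candidate region is an assay artifact when every
  sample *and* the negative control contain a reciprocally overlapping
  peak ("in all samples and the control" read conjunctively);
  qualifying candidates are merged. Blacklist filtering removes peaks
  overlapping any region by ≥1 bp.
* **Track correlation** tiles the genome into 200-bp bins, sums signal
  per bin, optionally drops all-zero bins (deepTools `--skipZeros`
  behaviour), and reports pairwise Pearson r.

## The molecular caliper

Core-motif scanning reports every occurrence of TGTC (orient F) and
GACA (orient R, a reverse-strand TGTC) on the forward sequence,
overlaps included; N never matches. Counting windows are 101 bp
(summit ±50) by default — the underlying description ("a 100 bp window
surrounding the summit") is ambiguous between 100 and 101, so the
width is a parameter and the Poisson reference uses whichever width is
in force (W−3 motif start positions).

An ordered instance pair maps to an orientation class by strand
pattern — (F,F) and (R,R) → DR (the latter is a direct repeat read on
the other strand), (F,R) → ER, (R,F) → IR — with the spacer counted
between the 4-mers. All three classes are invariant under reverse
complement of the window, which the property tests assert. Spectra are
built only from peaks whose window holds exactly two instances
(anything more makes the pairing ambiguous), normalized to sum to
100%. Note the literature's ER7/ER8 names count spacing between
TGTCTC 6-mers; a 4-mer spacer of 11 corresponds to ER7. No renaming is
performed here.

The random-window baseline draws uniform windows and also returns a
closed-form reference: with i.i.d. bases, both-strand core counts are
approximately Poisson with λ = 2·(W−3)·p_T·p_G·p_T·p_C from the
genome's base frequencies. The approximation ignores the
non-overlap constraint between occurrences and is good to total
variation < 0.02 at the scales used. Multi-motif enrichment is a
two-sided Fisher's exact test on (≥2 vs <2 instances) × (peak vs
random window).

The helical-phasing score projects a non-negative spacer profile onto
the complex tone exp(−2πi·s/10) over spacers 0–50 and normalizes the
squared magnitude by the squared total mass: 1 when all mass sits on
one phase class (e.g. spacers 7, 17, 27…), ~0 for a flat profile.
Signal-by-count reports per-bin medians/quartiles and Welch t-tests
between adjacent bins with raw p-values — no multiplicity correction,
matching how such pairwise comparisons are conventionally reported.

## Target genes and enrichment

Assignment windows are strand-aware: proximal = [TSS−1100, TTS+900],
distal = [TSS−10000, TTS+3000], mirrored for − genes. A peak
overlapping several windows goes to the gene with the smallest
summit-to-TSS distance (ties to the lexicographically smaller gene
id, for determinism). The headline "peak within 1 kb of the TSS" rule
is kept separate (symmetric ±1 kb around the TSS) and used by the
enrichment test; the two rules are deliberately not harmonized.
Co-occupancy labels each unique target gene A_only / B_only / both,
splitting "both" by whether any linked peak lies in a shared
consensus region. Peaks-within-10-kb counts summits within 10 kb of
the gene body span and compares groups by Welch's t-test; the random
background gene draw is seeded and recorded.

## Open chromatin

Peak/open-chromatin overlap is ≥1 bp. Tissue-specific regions have
zero ≥1-bp overlap with the union of all other tissues. The interval
Fisher test builds a 2×2 table from (peaks overlapping / not
overlapping the open set, open regions not overlapped, and a
no-overlap capacity cell). The capacity is `genome_length / (mean
peak length + mean open-region length)` minus the other three cells:
two uniformly placed intervals of mean lengths l_A and l_B collide
with effective length l_A + l_B, and this choice calibrates the table
to an odds ratio of ~1 under random placement (a construction using
the pooled mean length instead is biased high by ~2–3×). This is a
documented approximation of interval-association testing, not an
exact null model.

ATAC refinement tiles each primary region into 50-bp windows stepping
25 bp, anchored at the region start, keeping a final partial window
when it is ≥25 bp. Windows with mean per-base integration ≥25× the
average are retained and merged when gaps are ≤150 bp (the 150/151
boundary is tested exactly). The reference average is computed over
the whole track by default ("genome-wide average"); restricting it to
the primary regions is available via `average="primary"`.

## Sequence-to-signal model

Training sets pair one 201-bp summit-centred positive per peak
(labeled with the peak signal) with an equal number of 201-bp windows
sampled uniformly from peak-free sequence (labeled 0), split
train/test by seed. The regressor is a small convolution-plus-pooling
architecture: exact-match 4-mer detector filters sum-pooled into 256
k-mer counts, a structured second layer pooling core-motif
co-occurrences into orientation × spacer pair counts (spacers 0–15),
and a linear readout trained by stochastic gradient descent on
squared error for a fixed number of passes (35 by default). A
recurrent component is deliberately not part of the default: the
claims exercised here — clade-separable binding rules and the
percent-variance-explained matrix — do not depend on the exact
architecture, and a compact deterministic model keeps the pipeline
testable at desk scale. Pearson r on a zero-variance vector is
defined as 0, so degenerate cells are 0 rather than undefined; cells
with fewer than 3 test examples are missing. Model clustering is
average-linkage on distance 100 − symmetrized variance explained.
Element scoring predicts every 201-bp window (step 1) along an
element and reports the trapezoidal area under the prediction curve
divided by element length; a single-window element has zero area by
the trapezoid rule.

## Synthetic data: what it emulates and what it does not

Genomes are i.i.d. bases with a GC knob — sufficient to reproduce
random-window core-motif statistics to within a few percent, but
carrying no repeats, no isochores and no higher-order composition.
Planted elements are two cores in a chosen orientation with a fixed
spacer; spacer bases are drawn from the genome composition and
redrawn until the element scans to exactly its two cores, so planted
truth is exactly recoverable, while incidental background cores
elsewhere keep recovery tests honest. Elements never overlap each
other.

Peak families use a latent-site model: each element is a clade-A
and/or clade-B site (rate 0.45 per clade, coupled so that the
conditional cross-clade co-binding probability is the requested
`cross_clade_share`), and each TF binds its clade's sites
independently with probability `within_clade_share`. The expected
pairwise shared-peak fraction therefore equals `within_clade_share`
within a clade and `cross_clade_share` across clades, which the
acceptance tests check against binomial bounds. Signal is
(base + β·motif count in the summit window) with multiplicative
lognormal noise — read-depth-like positivity and right skew; with
zero noise the signal is strictly increasing in motif count.

Expression tables mark `n_up` induced genes sampled with weight
`prox_effect` when a clade-A peak lies within 1 kb of the TSS (weight
1 otherwise), so `prox_effect = 1` is an exact null for the
enrichment test and large values make the enrichment recoverable.
Open-chromatin sets are non-overlapping common + tissue-specific
regions, so specific-region recovery is exact. Every generator is a
pure function of its arguments including the seed.

Because the genome model is i.i.d. and peak placement is tied
directly to planted elements, passing tests demonstrate the
correctness and calibration of the *operations*, not performance on
real maize data: real peak sets carry repeat-driven artifacts,
composition biases and unmodeled binding determinants that these
simulations do not attempt to reproduce.

## Problem sizes and numerical choices

The bundled analysis runs on a 2-Mb genome with ~1,900 planted
elements, ~400 peaks per TF, 1,200 genes and 50,000 random windows —
sizes at which every stage completes in seconds while binomial errors
stay a few percent. The null-calibration check uses an 8-Mb genome
with a 4,000-gene universe and 800 induced genes so that the Fisher
p-value's discrete atoms (~0.03) are fine enough for a meaningful
Kolmogorov–Smirnov uniformity test over 200 replicates. Training runs
are 35 SGD passes with standardized features and labels; all
randomness flows through explicit integer seeds.
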