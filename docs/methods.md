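# Methods

## Peak handling

Coordinates are 0-based half-open everywhere (BED convention); narrowPeak
summit offsets are converted to absolute coordinates on read, and a
summit column of −1 means "no summit".  Normalization trims or extends
each peak to a constant odd length *L* with the center base — the summit
when present, otherwise the midpoint — at index (L−1)/2, i.e. the
interval [c − (L−1)/2, c + (L−1)/2 + 1).  Odd lengths are required so a
unique center base exists; 201, 401 and 1001 bp are the lengths used
throughout (201/401 for over-representation runs, 1001 for zone
estimation, which needs distal flanks to expose the background match
rate).  Peaks whose normalized interval would overrun chromosome bounds
are skipped, not clipped, so that every extracted sequence has identical
length; the skip count is logged and recorded in provenance.

Replicate experiments are pooled by chaining summits per chromosome in
ascending order: consecutive summits within the pooling distance (500 or
1000 bp) join one region, so chains longer than two peaks collapse into a
single region.  A region is *replicated* when it contains at least one
peak from each replicate.

## Motif model

Position frequency matrices (PFMs) are parsed from JASPAR-style text
(Bio.motifs does the parsing; row labels are honoured, output rows are
always A, C, G, T).  Conversion to a position weight matrix uses base-2
log-odds with the square-root pseudocount rule: for column *i* with total
N_i and background probability p_b (uniform 0.25 by default),

    w[b,i] = log2( ((n[b,i] + √N_i · p_b) / (N_i + √N_i)) / p_b ).

The *relative score* of a width-w window is 100·(raw − min)/(max − min),
where min/max are the column-wise minimal/maximal raw sums — a strictly
increasing affine map of the raw score, bounded in [0, 100] and attained
exactly by the per-column argmin/argmax sequences.  Non-ACGT bases score
as the column minimum (the most conservative choice; the matrix carries
an explicit fifth row for this).

Scanning scores every offset on both strands (the reverse strand via the
reverse-complement matrix on the same coordinates).  Discrete hit lists
are built greedily in descending score, ties broken by leftmost offset
then + strand; a candidate is rejected if it would overlap an accepted
hit by more than ⌊w/5⌋ bp, so a 7 bp motif may overlap a neighbour by
1 bp.  A hit's distance to the peakMax is measured from the motif
*center* (offset + ⌊w/2⌋) to the sequence center; anchoring at the center
rather than the start keeps the distance convention width-independent.
The default score floor for retained hits is 60 so landscape plots show
the sub-threshold background; it is configurable.

## Background generation

Six models match a target set's composition at different granularities,
plus a Markov generator:

| model | matches | default parameters |
|---|---|---|
| `mono_shuffle` | exact base counts per sequence | — |
| `di_shuffle` | exact dinucleotide counts per sequence | — |
| `gc_match` | global GC, drawn from a genomic pool | 1-point GC bins |
| `mono_shuffle_window` | base counts at window scale | window 100 bp, step 50 bp |
| `di_shuffle_window` | dinucleotide counts at window scale | window 100 bp, step 50 bp |
| `gc_match_window` | window-GC profile, from a pool | window 100, step 50, ±1 point global-GC band |
| `markov` | (k+1)-mer statistics of the whole set | order 3 |

The dinucleotide shuffle draws a uniform random Eulerian path on the
symbol multigraph (random last-exit edges retried until they form an
arborescence toward the final symbol, then randomly ordered remaining
edges), which preserves all overlapping pair counts, the length, and the
first and last characters exactly.  N is a fifth symbol in shuffles and
is excluded from both numerator and denominator of GC content.  Window
defaults of 100/50 bp are sub-peak scale with overlapping coverage.  The
Markov model is trained single-strand on the targets as given, with
add-one smoothing and the initial state drawn from the observed k-mer
distribution; order 3 (4 bp words) matches local composition without
memorising whole binding sites, which higher orders would.  Genomic pools
are built by merging the supplied regions and tiling each merged region
left-to-right into non-overlapping pieces, discarding the remainder.
GC-matching draws without replacement; an exhausted GC bin falls back to
the nearest non-empty bin (ties toward lower GC) with the substitution
count logged.  One background sequence per target (k = 1) is the default.
All generators are reproducible from a single integer seed.

## Over-representation and bias measures

The over-representation score is deliberately simple: a sequence is a
*hit* for a profile when it contains at least one placement with relative
score ≥ 85 (the conventional cut-off separating curated binding sites
from background); the score is −log10 of the one-tailed Fisher exact
p-value of the hit/no-hit × foreground/background table, testing
foreground enrichment.  This is a self-contained scorer, not a
re-implementation of any published over-representation suite; the bias
diagnostics only require a score monotone in enrichment, and their
behaviour (skew under composition mismatch, its removal under matching)
does not depend on the particular monotone transform.  Scores that
overflow to +∞ (p underflows to 0) are capped at max(500, largest finite
score + 100), an idempotent, order-independent rule.

Bias diagnostics: *skew* is the negative slope of the ordinary
least-squares fit of score on profile GC content — on a GC-rich
foreground against a genome-like background the slope is positive
(GC-rich profiles inflated), i.e. the skew is negative, and the more
negative the skew the stronger the composition bias.  *Top-5 recovery*
asks whether the assayed TF's own profile ranks among the five largest
scores (ties broken by score, then id).  The *non-outlier mean/SD*
removes scores above mean + 1 SD (computed over all scores, sample SD)
and reports the mean and SD of the remainder; a well-matched background
leaves both small.  CB plots scatter score against profile GC with a
dotted reference line at 100 (an arbitrary visual anchor) and the skew in
the title; the underlying table is exported as TSV.

## Enrichment zone and score threshold

Distance bins: the absolute distance of each peak's *top* motif (one per
peak) to the peakMax is binned at 5 bp out to 500 bp; bin k covers
((k−1)·5, k·5] with a distance of exactly 0 counted in the first bin, and
proportions use the full peak count as denominator.  The background range
is (200, 500] bp (60 bins).  A least-squares line is fitted there
(x = bin upper limit, y = proportion); the *allowance offset* is twice
the third-largest signed residual after omitting the two largest —
residuals are taken in descending signed order, and the offset is floored
at 0 so the allowance line never sits below the fit.  The one-sided
distance threshold is the upper limit of the outermost proximal bin
(≤ 200 bp) whose proportion exceeds the allowance line at that bin
(enrichment out to the 100–105 bp bin gives a 105 bp threshold); the zone
width is twice the threshold.  If no bin qualifies the dataset is flagged
not enriched.

Score bins: top motif scores are binned at 1 point (bin 81 covers
80 < s ≤ 81).  *Central* bins count peaks whose top motif lies inside
the zone; *control* bins count each peak's best motif inside the distal
flank windows |d| ∈ (200, 200 + T] on both sides — the same total width
as the zone, placed entirely inside the background range (T ≤ 200
guarantees the fit).  Control placement is deterministic.  Bin *i*
*passes* when central[i] − control[i] > f · max(control[j], j ≥ i) with
signal fraction f = 0.20 by default (0.05 is also reported); the suffix
maximum prevents sparse low-score bins from qualifying.  Scanning from
high to low scores, the *flagged* bin is the lowest passing bin contained
in some run of 5 consecutive bins of which at least 4 pass — the
neighbourhood support that keeps an isolated noisy bin from setting the
threshold.  A strictly centered 5-bin window was the alternative reading;
it was rejected because it can skip past the true lowest signal bin when
the signal occupies an exact half-window (a step starting at bin b would
flag b+1, not b), and the any-containing-run form preserves monotonicity:
raising f never lowers the threshold.  The reported score threshold is
the label of the bin one point above the flagged bin, and a motif is
*above threshold* when its relative score strictly exceeds the flagged
bin's label — scores inside the flagged bin itself are excluded.  This
exclusive boundary is deliberate and conservative; see Limitations.

Classification: a peak is *direct* when at least one placement (any rank)
lies within the zone and scores above threshold; otherwise
*undetermined*.  Zone estimation uses only rank-1 motifs; classification
uses the best score anywhere in the zone.

Replicate concordance: pooled regions are cross-tabulated
replicated/unique × direct/undetermined; replicated regions whose two
replicates disagree on the label are omitted (they are rare; the count is
recorded) and a one-tailed Fisher exact test asks whether direct regions
are enriched among replicated ones.  The exact p of a discrete test is
conservative (P(p ≤ α) ≤ α, with E[p] > 1/2); a `midp` option subtracts
half the observed table's point probability, the standard correction when
a near-uniform null distribution is wanted, e.g. for calibration checks.
Per-TF summaries across datasets report the mean and the mean pairwise
absolute difference (0 for a single dataset) of zone widths, score
thresholds and direct fractions.

## Views

"Density" means a normalized histogram at the stated resolution — 2 bp
for the all-peaks distance density, 5 bp for the strong-motif subset
(relative score ≥ 85), 10 bp for inter-motif distance histograms — not a
kernel estimate; an optional moving-average flag exists for multi-profile
overlays.  The bi-motif view plots, per peak, the second motif's center
minus the primary's center (x) against the primary's distance to the
peakMax (y); homotypic (second-best of the same profile) and heterotypic
(best of another profile) pairs share the code path, and the scanner's
overlap restriction produces the characteristic gap around x = 0.  The
dinucleotide-environment view aligns sequences on the anchor motif's
center, reverse-complementing minus-strand anchors so the motif reads one
way, and reports at every offset the proportion of sequences carrying
each of the 16 dinucleotides; pairs containing N are excluded from
numerator and denominator, per-position denominators track coverage, and
the default ±400 bp flank covers the repeat-scale features such analyses
target.  Every view exports its numbers as TSV before rendering.

## Synthetic data

The generators define the study conditions for all tests:

* `make_peak_dataset(n, pfm, f, length=1001, placement, min_site_score=90,
  gc=0.40, seed)` — a fraction *f* of peaks receives one site sampled
  column-wise from the PFM's normalized counts, rejection-sampled to a
  relative score ≥ `min_site_score`, inserted on a random strand at a
  center offset drawn from the placement law (uniform ±d or normal σ)
  around the peakMax; the rest are i.i.d. background at genome-like 40%
  GC.  Truth tables record exactly what was planted where.
* `make_bimotif_dataset` plants a primary site at the peakMax and a
  second site at a signed spacing (± jitter), refusing geometries where
  the sites would overlap beyond the scanner's bound.
* `make_gc_biased_collection` draws a GC-rich foreground (per-sequence
  GC ~ Beta(12, 8), mean 0.60), a genome-like background (Beta(8, 12),
  mean 0.40) and a pool spanning GC 0.2–0.8 — with *no* planted motifs —
  reproducing composition-driven over-representation bias and its removal
  under GC matching.
* `example_pfm` builds profiles with heterogeneous column specificities
  (fixed deviations around a mean of 0.85, uneven splits of the
  off-consensus mass).  Homogeneous columns would admit only ~w distinct
  raw scores, collapsing the 1-point score bins into isolated spikes that
  the threshold scan's 4-of-5 neighbourhood rule can never support;
  curated profiles are heterogeneous, and the quasi-continuous score
  distribution is the realistic condition.  `gc_spanning_pfms` lowers the
  mean specificity to 0.70 so match rates track sequence composition, as
  needed for bias demonstrations.

What the synthetic data does *not* emulate: read-level signal and peak
calling, repeat elements and other non-stationary genomic structure,
correlated summit error, or co-factor motif grammar.  Passing tests
therefore demonstrate correctness of the algorithms under their stated
assumptions, not performance on any particular organism's data.

## Problem sizes and numerical choices

The test suite runs zone/threshold recovery at n = 5000 peaks of 1001 bp
(30 runs), exhaustive Fisher-vs-hypergeometric agreement for all 2×2
tables with total ≤ 50 (|Δ log10 p| < 1e−9), brute-force relative-score
enumeration at widths ≤ 6, exact shuffle invariants over 1000 sequences
of 50–1001 bp, and 20-seed paired bias-correction and 100-seed null
calibration checks; these sizes were chosen to give stable proportions
(binomial SE ≲ 0.007 at n = 5000) on a single CPU.  Scanning is
vectorized over a batch score matrix (n × offsets × 2 strands), with the
greedy hit selection applied only where discrete hit lists are needed.
Degenerate inputs: sequences shorter than the motif yield empty hit lists
with a warning; an all-infinite score vector caps at 500 with a warning;
a concordance table with an empty margin returns NaN with a warning
rather than raising.

## Limitations

* The direct fraction is biased slightly low by design: sites whose top
  scan score falls inside the flagged score bin are excluded by the
  exclusive threshold boundary.  Under the recovery conditions above
  (planted fraction 0.6, site scores ≥ 90) the recovered fraction is
  0.55–0.57, the missing ~4–5 points being exactly the planted sites in
  the lowest signal bin.  The inclusive alternative (accepting the
  flagged bin) would undo this but contradicts the threshold's definition
  as the bin *above* the flagged bin.
* The allowance line is a noise floor estimated from 60 distal bins; in
  roughly 1 run in 30 at n = 5000 a single noisy proximal bin beyond the
  planted span exceeds it and inflates the zone by one or more bins.
* The over-representation score scale is specific to this package's
  Fisher formulation; only orderings and the bias measures, not absolute
  score values, should be compared across tools.
* The exact concordance p-value is conservative; use `midp=True` when a
  uniformly calibrated quantity is required.
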