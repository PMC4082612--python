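# peaktopo

Topological analysis of transcription-factor binding sites (TFBSs) in
ChIP-Seq peaks.

ChIP-Seq returns genomic regions ("peaks") enriched for a protein's
binding, but a peak does not say *why* the region was pulled down.  When
the assayed TF binds its own recognition sequence, matches to the TF's
position weight matrix (PWM) concentrate tightly around the read-frequency
maximum of the peak (the summit, or *peakMax*); indirectly captured
regions show only the genomic background rate of matches.  `peaktopo`
exploits this topology for two recurring problems in regulatory genomics:

1. **Composition bias in motif over-representation.**  Peak sets are
   typically GC-rich relative to the genome, and PWM hit rates track
   sequence composition, so a naive background inflates GC-rich profiles
   regardless of binding.  `peaktopo` generates composition-matched
   backgrounds (mono- and dinucleotide shuffles, whole-sequence or in
   sliding windows; GC-matched draws from a genomic pool, global or
   windowed; a k-th-order Markov generator), scores over-representation
   with a per-sequence Fisher exact test, and quantifies residual bias via
   composition-bias (CB) plots and the *skew* statistic — the negative
   slope of the over-representation-score vs profile-GC regression.
2. **Direct-binding classification.**  A heuristic algorithm estimates,
   per dataset, the *enrichment zone*: using 5 bp bins of the absolute
   distance between each peak's top motif and the peakMax, it fits a
   regression line to the distal background bins (200–500 bp), raises it
   by twice the third-largest residual (an *allowance line*), and takes
   the outermost proximal bin still above the allowance as the one-sided
   distance threshold.  An analogous scan over 1-point motif-score bins
   (zone vs width-matched distal control windows) yields a PWM score
   threshold.  Peaks with a motif inside the zone above the score
   threshold are labelled *directly bound*; the rest are *undetermined*.

Scoring uses the relative PWM score, `100·(raw − min)/(max − min)` in
base-2 log-odds, so thresholds are comparable across motifs.  Reported
motifs may overlap by at most one fifth of the motif width.  Spatial
diagnostics (TFBS-landscape, bi-motif and dinucleotide-environment views)
are computed as data tables first and rendered with matplotlib second.

A fully seeded synthetic-data module generates peaks with planted binding
sites at controlled offsets, fractions and scores, genomic pools with
controllable GC distributions, and GC-biased foreground/background pairs,
so every claim the package makes is testable against known ground truth.

## Worked example

```python
import numpy as np
from peaktopo import background, hadb, motifs, overrep, synthetic

# a peak collection in which 60% of peaks carry one planted site,
# uniformly placed within +/-100 bp of the summit
pfm = synthetic.example_pfm()                      # 8 bp profile, consensus TGACGTCA
pwm = motifs.pfm_to_pwm(pfm)
_, seqs, truth = synthetic.make_peak_dataset(
    3000, pfm, f=0.6, placement=("uniform", 100), min_site_score=90, seed=1
)

res = hadb.run_hadb(seqs, pwm, seed=1)
print(res.zone.distance_threshold, res.zone.width, res.score_threshold,
      round(res.direct_fraction, 3))
# 100 200 92 0.552
```

The heuristic recovers the planted 100 bp placement half-width exactly
(one-sided threshold 100 bp, zone width 200 bp), sets the relative-score
threshold at bin 92, and calls 55.2% of peaks directly bound — slightly
under the planted 60% because sites whose top scan score falls at or
below the flagged score bin are excluded by construction.

Composition bias and its correction:

```python
pfms = synthetic.gc_spanning_pfms()                    # profiles spanning GC 0.2-0.8
fg, naive_bg, pool, _ = synthetic.make_gc_biased_collection(n=100, seed=1)
t_naive = overrep.score_overrepresentation(pfms, fg, naive_bg)
matched = background.match_gc(fg, pool, rng=np.random.default_rng(1))
t_match = overrep.score_overrepresentation(pfms, fg, matched.sequences)
print(round(overrep.eval_skew(t_naive), 2), round(overrep.eval_skew(t_match), 2))
# -12.69 -0.05
```

No motif is planted here, yet the GC-rich foreground scored against a
genome-like background shows a strong skew (GC-rich profiles inflated);
drawing the background from the pool with per-target GC matching removes
it.

The same pipelines are available from the shell:

```sh
peaktopo simulate --n 3000 --f 0.6 --placement uniform:100 --seed 1 --outdir sim
peaktopo hadb sim/peaks.fa --pfms pfms.txt --seed 1 --outdir out
peaktopo biasaway targets.fa --model di_shuffle --seed 42 --outdir bg
peaktopo view landscape sim/peaks.fa --pfms pfms.txt --outdir fig
```

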