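# Methods

This note documents the models, parameter choices and numerical decisions
behind cgikit, and what the synthetic-data experiments do and do not show.

## Cluster detector

**Null model.** Within one chromosome of length L with n CpG starts, the
null assumes CpG starts occur as a Bernoulli process with per-position
probability p̂ = n/(L−1), so distances between consecutive starts are
i.i.d. geometric on {1, 2, …}. Each chromosome is processed independently;
p̂ and the distance threshold are never pooled across records, mirroring
per-sequence genome runs.

**Statistic.** For a cluster of N CpGs the span S = last_start −
first_start is the sum of N−1 distances, so P(S′ ≤ S) is the CDF of
(N−1) + NegBin(N−1, p̂), computed via scipy's `nbinom.cdf` (regularized
incomplete beta). Tests require agreement with naive enumeration to 1e-12
on a small grid. A singleton has no distances and no statistic, hence
`min_cpgs = 2`. In real DNA the minimal CpG distance is 2 (CG cannot
overlap itself); the null nevertheless keeps support {1, 2, …} — internal
consistency with the enumeration oracle is the contract, and the effect on
tail probabilities is negligible at genomic p̂. P-values that underflow to
zero are floored at a subnormal constant so logarithms stay finite.

**Distance threshold.** The percentile of the consecutive-distance
distribution is exposed (`distance_percentile`, default the median, the
method's customary choice; nothing in the evaluated setting pins a
different value). With an even number of distances the midpoint average is
floored; the result is floored at 2. Distances *equal* to the threshold
cluster; a `strict_distance` flag excludes equality, because this tie rule
measurably changes island counts.

**Reporting.** Island coordinates run from the first CpG's C to the last
CpG's G (span + 2); the +2 is presentation only — the statistic is over the
span. Reported islands are disjoint by construction (clusters partition the
CpG sequence) and gaps between them exceed the threshold. No multiple-
testing correction is applied; the 1e-5/1e-20 thresholds are used as given.
Chromosomes with fewer than two CpGs yield an empty prediction rather than
an error, so multi-record genomes stream through.

## Sliding-window detector

The five-step search (slide 1 bp → jump by whole windows → roll back 1 bp →
trim to a passing segment with CpG ends → merge across gaps ≤ 100 bp with
re-verification) is implemented over prefix-sum composition arrays, so
window and segment checks are O(1) and whole-chromosome scans are
vectorized. Defaults: window = min_length = 500 bp, GC ≥ 55%, O/E ≥ 0.65,
n_CpG ≥ 0.6·L/16 evaluated on the segment's own length (the guard against
"mathematical" islands), merge gap 100 bp; all exposed as parameters and
logged in output BED headers, because island counts are sensitive to them.
Trimming anchors island ends on a CpG (C of the first, G of the last),
making coordinates comparable with the cluster detector. Merging is
refused when the gap consists entirely of Ns of merge-gap size or more, and
when the merged segment fails re-verification; every reported island
therefore satisfies all criteria over its full extent — the origin of the
threshold-biased property distributions.

## Interval statistics and benchmarking

All coordinates are 0-based half-open; overlap always means ≥ 1 shared
base, so touching intervals do not overlap. Coverage is computed against
the per-chromosome union of elements (split-invariant, order-invariant);
overlap queries use searchsorted on sorted disjoint arrays and are verified
against per-base brute force in tests. "Inner islands per outer island"
uses overlap, not strict containment — containment is available by flag.
Sensitivity mixes prediction-side TPs with gold-side FNs
(SN = TP/(TP+FN), FN = gold − touched); this heterogeneous reading is the
one that reproduces all published table cells from their count quadruples.
PPV = TP/n_predicted is a lower bound: with no complete gold standard,
every non-overlapping prediction is counted false. Calibration sorts by
p-value and cuts at the target size, including all exact ties at the cut
(reported), so filter-at-threshold recovers the selection up to ties.

## Methylation

Per-tissue labels: mean ≥ 80 methylated, < 20 unmethylated, else
intermediate (boundaries: 80 → methylated, 20 → intermediate, from the
half-open phrasing of the rules). A tissue's record is usable when
supported by ≥ 2 clones; samples within a tissue are averaged before
labeling; CpGs with < 6 usable tissues stay unclassified. Cross-tissue
states use strict majorities with absolute vetoes: one unmethylated tissue
vetoes a methylated call regardless of the majority (and vice versa); when
both extremes occur and intermediates are in the minority the CpG is
differential — which means a 5-methylated/1-unmethylated CpG is
*differential*, the literal consequence of the veto-plus-differential
rules. Island labels require classified states for more than half of the
island's CpGs; majorities are then taken over the classified CpGs (the only
reading consistent with the worked rule examples), with the same vetoes.

Read-style island means use cytosines with ≥ 10 reads, strand rows averaged
per CpG, and are undefined unless strictly more than half of the island's
CpGs are covered. Two-tissue array regions are unmethylated at scaled 5mC
log2 ratio < 0.3; the methylated side of a differential call is the
complement (≥ 0.3), which the source rules leave implicit.

Heterogeneity of a window island hosting ≥ 2 cluster islands is the
maximum over tissues and inner-island pairs of the difference between
inner-island mean methylations; "maximal difference over the different
tissues" is ambiguous between max-over-tissues and per-tissue reporting, so
the maximum is reported along with a per-tissue breakdown. The
Mann-Whitney island-pair test is exact (exhaustive enumeration of label
assignments, two-sided p = twice the smaller tail, correct under ties) when
both sides have ≤ 7 values, and uses the tie-corrected normal approximation
above that; significance is p ≤ 0.05.

## Expression

Expressed means signal > 200 (strict). The coexpression value is the
fraction of concordant tissues among tissues with data for both genes;
tissues missing either signal leave numerator and denominator. Classes:
divergent ≤ 0.2, coexpressed = 1.0, intermediate otherwise.

## Synthetic data

`simulate_genome` samples i.i.d. bases at the configured GC fraction,
destroys spontaneous CG dimers, then injects CG dimers by a Bernoulli
process (0.002/bp background, 0.08/bp in islands by default) skipping
overlaps — so inter-CpG distances match the geometric null exactly, which
is what makes the analytic recovery checks interpretable. Planted islands
(100 of mean 500 bp, sd 100, floor 250 on a 2 Mb chromosome) are placed in
evenly spaced slots with jitter, guaranteeing separation. Background GC is
38% (mammalian-like), island GC 60%; a demonstration configuration with
island GC 45% produces CpG-dense but AT-leaning islands that only the
cluster detector can see, used to exhibit the sub-threshold island
property. Methylation tracks put background CpGs at 85–95%, unmethylated
islands at 5–15%, and split differential islands across the halves of a
12-tissue panel (the size of the reference amplicon panel), with Gaussian
noise (sd 3 points) and a 10% fraction of single-clone records to exercise
the filters. Expression uses a 73-tissue panel with off signals in
(20, 150) and on signals in (300, 5000).

What the simulations do **not** emulate: isochore and repeat structure,
Alu-driven spurious CpG richness, CpG-density autocorrelation beyond the
planted segments, assembly gaps beyond simple N handling, realistic
clone-count distributions, probe-level microarray noise. Passing the
recovery experiments therefore shows the algorithms implement their
definitions and separate signal from a geometric-null background; it does
not certify genome-scale precision on real assemblies, where repeat
structure dominates the false-positive landscape.

## Problem sizes

Recovery experiments run on a 2 Mb genome with 100 planted islands (the
standard condition for the planted-recovery criterion), the methylation
experiment on 400 kb with 30 islands and 12 tissues, the low-GC
demonstration on 500 kb with 25 islands, and the brute-force oracle checks
on ≤ 10 kb instances — sizes chosen so the whole suite and the acceptance
script each run in well under a coffee break on one core while keeping the
statistics comfortably away from their acceptance margins.

## Known limitations

- Case is normalized on input: repeat-masked (lowercase) sequence is used
  like any other sequence, and ambiguity codes collapse to N.
- The window detector's search is sensitive to its step/rollback/merge
  conventions; ours are documented above and logged in output headers, but
  other implementations may count islands slightly differently.
- The cluster p-value is not corrected for multiple testing across
  clusters.
- `swa_heterogeneity` filters records by the amplicon clone rule; read-
  style inputs should be pre-filtered to ≥ 10 reads before being passed in.
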