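# Methods

This note documents the models and procedures `endshift` implements, the
parameters that matter, the numerical choices made where the procedure
leaves room, and what the simulation-based tests do and do not establish.

## Differential 3′-end test

**Model.** Each locus is treated as a mixture over (unknown) poly(A)
sites; a read's aligned 3′ end is a draw from that mixture plus local
positional noise. Replicates are pooled within condition, so the test
compares two empirical distributions of 3′-end positions. The test
statistic is the Wasserstein-1 distance between the two empirical CDFs,
computed by exact CDF integration over the merged support. It is in
nucleotide units, supports unequal sample sizes, and satisfies the metric
axioms (symmetry, identity of indiscernibles at the level of empirical
distributions, triangle inequality) — all property-tested.

**Permutation null.** Read labels are shuffled between conditions,
preserving the two sample sizes, and the EMD recomputed (999 permutations
by default). Because the pooled multiset is fixed, the EMD of a
permutation depends only on which *sorted* positions carry the treatment
label; the implementation exploits this to vectorise all permutations as
one cumulative-sum matrix operation. Shuffling is without replacement
(a permutation, not a bootstrap), matching the description of reads being
shuffled between samples.

**Tail model.** A gamma distribution with location fixed at 0 is fitted
to the null EMDs by maximum likelihood (`scipy.stats.gamma.fit(floc=0)`;
a method-of-moments option exists) and `p` is the gamma survival function
at the observed EMD. Fixing the location at 0 reflects that EMD is
non-negative and 0 under exact equality. The gamma is used for its tail
resolution — with 999 permutations the empirical p cannot go below
1/1000, while the gamma tail interpolates far smaller values, which
matters after multiple-testing correction across thousands of loci. The
fit is declared degenerate when the null has zero variance, contains
non-positive values, or the optimiser fails; the test then falls back to
the empirical estimator `p = (1 + #{null ≥ obs}) / (n + 1)`. Calibration:
the empirical-mode p-values are uniform under the null (KS-tested); the
gamma-mode p-values are a good tail approximation but, being a parametric
smooth of a discrete null, deviate slightly in the body of the
distribution — acceptable because decisions are made in the tail, and the
observed false-call rate on null simulations is far below nominal.

**Decision rule.** Benjamini–Hochberg correction across tested loci;
a locus is called when EMD > 25 nt and FDR < 0.05, both strict
inequalities. The 25-nt floor suppresses statistically significant but
biologically trivial jitter at high read depth. Direction is the sign of
(mean treatment 3′ position − mean control 3′ position), negated on the
minus strand so that positive is always distal in the direction of
transcription. A significant locus with an exactly zero mean shift (a
measure-zero tie on integer data) is classified distal; loci with fewer
than `min_reads_per_condition` (default 10) reads in either condition are
carried through as `untested` with no p-value.

**Reproducibility.** Each locus gets an RNG substream derived from
(seed, SHA-256 of the locus id), so results are byte-identical for a
fixed seed and independent of locus iteration order.

## Read handling

GTF/GFF3 records sharing a gene/locus key are merged into union loci;
coordinates are 0-based half-open internally, BED on output. Alignment
filters: largest single indel ≤ 4 nt (inclusive — the rule removes
indels *greater than* 4 nt), minimum MAPQ, primary-only. A read is
assigned to the same-strand locus it overlaps most, ties broken by
lexicographically smallest locus id; how the original analysis resolved
multi-locus overlaps is not specified, so this deterministic rule is our
choice. The 3′ end is the alignment end (soft clips excluded). 3′ ends
falling outside the assigned locus ± `flank` (default 0) are counted and
reported, never silently dropped. Splice-junction counting is
exact-coordinate by design.

## Oversplit filtering

Nanopore oversplitting segments one molecule's signal into several reads,
creating false internal 3′ ends. Two reads are chained when they share a
pore channel, are consecutive in the channel's temporal order, and map to
the same chromosome and strand within 1 kb (nearest alignment
boundaries); chains are maximal runs of this relation. "Consecutive" is
adjacent temporal rank with no absolute time cap by default (an optional
`max_time_gap` exists). The same-strand/same-chromosome requirement is
stricter than bare 1-kb proximity but follows from the fragments being
one molecule. The kept member is the most 3′ in transcriptional
orientation — native RNA enters the pore 3′ end first, so the earliest
fragment carries the genuine 3′ end; coordinate ties go to the
later-sequenced read (a documented heuristic). The filter is idempotent
and order-invariant, both tested.

## Coverage segmentation

Within a locus, replicate coverage profiles are scaled so each area
equals the mean area (zero profiles untouched; an all-zero locus is
skipped and reported). Expressed regions are maximal runs where the mean
normalised coverage across all samples is ≥ 1. The two-fold-in-25-nt
differential criterion is operationalised as: per-position log-ratio
`r = log2((trt + 1)/(ctl + 1))` (pseudocount configurable); a position is
a boundary candidate when the range of `r` over the trailing 25-nt window
reaches log2(fold); candidate runs closer than the window are merged and
represented by the steepest one-step change, which is exactly the step
position for clean steps. Segments shorter than 50 nt are merged into the
neighbour with the closer mean log-ratio (preserving coverage rather than
deleting it). Whether the original comparison used raw or log ratios and
how boundaries were merged is unspecified; these are our documented
choices. Fragment counting takes properly paired primary pairs, one count
per pair, with multi-assignment by default and a largest-overlap-only
option; the counts table is exported for external differential-usage
tools (e.g. DEXSeq) — fitting those models is out of scope here.

## Enrichment and association

Domain enrichment shuffles domain assignments between tested loci by
applying a random bijection of loci to the whole assignment table
(19,999 permutations by default). This preserves the assignment multiset
and per-locus domain counts — the strictest reading of "shuffled between
tested loci". The statistic is the number of significant loci carrying
the family; p uses the (1+k)/(1+n) convention, BH-corrected across
families. An exhaustive mode enumerates per-family placements for exact
verification on small inputs. The 2×2 association test is Pearson
chi-square with Yates continuity correction: on the NLR contingency
tables reconstructed from published counts (44/30/18/32 and 20/8/42/54)
it reproduces p = 0.02 at two decimals, whereas the uncorrected test
gives 0.01 — the basis for inferring that the original analysis used the
correction. Group differences use Welch's unequal-variance t-test;
sliding-window metrics (e.g. 5-kb synteny diversity) are assigned to loci
by maximal overlap with smaller-coordinate tie-breaks.

The manual-annotation screen (`sop_screen`) encodes the expressed /
multi-site / APA-candidate rules: expression requires coverage in ≥ 2
conditions, a poly(A) site cluster requires ≥ 4 pooled reads, and
candidacy requires a site's usage proportion to change ≥ `coverage_fold`
between conditions. Clustering is single-linkage with a 13-nt window —
the visual procedure has no numeric window, so this surrogate (about half
the EMD call threshold) is a documented choice.

## Synthetic data

The generator draws, per locus and condition, Poisson(depth) reads; each
read picks a site from the condition's weight vector and adds rounded
Gaussian jitter, truncated to the locus. Default conditions: depth 30
reads/condition, jitter 5 nt, 2-kb loci; shifted loci swap the major
weight 0.8→0.2 between two sites 200 nt apart, giving an analytic
population EMD of 0.6 × 200 = 120 nt. These depths are typical of
moderately expressed genes in a direct RNA sequencing run, and 200 nt is
a realistic proximal-to-distal site separation (intronic or 3′UTR
alternatives). Coverage simulations use piecewise-constant means (base
10×), Gaussian noise (sd 0.5) and optional per-replicate library-size
factors; oversplit injection splits 20 % of reads into 2–3 same-channel
consecutive fragments with sub-kilobase gaps, most-3′ fragment sequenced
first. Problem sizes in the test suite (1000 null + 100 shifted loci for
calibration and power) keep the full suite under a minute while giving
binomial standard errors below 3 % on the power estimate.

What the simulations do **not** emulate: basecalling and alignment error,
reference bias and multi-mapping, truncated reads from RNA degradation or
pore ejection (which create genuine-looking internal 3′ ends that are not
poly(A) sites), splicing isoforms, overdispersed replicate structure, and
correlated oversplitting hotspots. Passing tests therefore demonstrate
correctness of the statistics and algorithms under their stated model,
not robustness to every artifact of real nanopore data — the oversplit
filter and the EMD floor are the two guards carried over from practice.

## Known limitations

* Two conditions only; replicates are pooled, so replicate-level
  biological variability does not enter the null (a locus with strong
  between-replicate heterogeneity can be called on a pooled difference).
* The gamma tail is an approximation; extremely small p-values are
  extrapolations beyond the 999 permutations that support them.
* Maximal-overlap read assignment can misattribute reads at overlapping
  same-strand loci (readthrough/chimeric transcripts), which is precisely
  where interesting biology may occur; inspect called loci near
  neighbours.
* Segmentation assumes steps ≥ ~2× the window apart; closer boundaries
  merge.
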