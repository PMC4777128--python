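# Methods

## Site prediction

A PWM is a per-position base-probability matrix. On loading, counts or
frequencies get a pseudocount of 1% of each row's total (floored at
0.01) and are renormalized, so every entry is strictly positive and
log-space scoring is safe. `adjust_background` attaches a species'
base composition for log-odds reporting; site calling itself uses the
*relative affinity* — the ratio of the window's frequency product to
the per-column-maximum (consensus) product — which is background-free.
A window is a site when its relative affinity is at least 1/25 (the
`fold_cutoff` default, a deliberately conservative threshold that
trades sensitivity for precision). Scoring is done in log space with a
1e-12 slack on the threshold comparison so exact-boundary sites are
not lost to rounding.

Promoters are the 600 bp immediately upstream of each annotated gene
start ("coding region" and "translational start" are treated as the
same anchor throughout, including the ChIP module), clipped only at
chromosome ends — not at upstream neighbours. Coordinates are 0-based
half-open everywhere internally; GFF3 input is converted from 1-based
closed. Both strands are scanned; minus-strand sites carry the
leftmost promoter coordinate. Windows containing N are skipped rather
than penalized. When a perfectly palindromic window passes on both
strands at the same start, one + strand record is kept so spacing
statistics do not double-count; a consequence is that the
(start, strand) set is not monotone in `fold_cutoff` even though the
start set is, and that palindromic motifs carry no usable strand
information (the synthetic fixtures therefore use non-palindromic
consensus words).

## The co-occurrence screen

For a heterotypic motif pair, every non-overlapping (A-site, B-site)
pair within a promoter contributes one count at its edge-to-edge gap
*d*; overlapping site pairs (negative gap) are discarded, consistent
with B = 600 − (width_A + width_B) being the largest achievable gap.
All co-occurring site pairs are counted, not only nearest pairs,
because the permutation null counts the same way. Homotypic pairs are
excluded; with 196 motifs the hypothesis space is C(196,2) = 19,110.

The genome-wide null shuffles the motif labels over all site slots,
preserving each motif's total and each promoter's slot geometry. A
slot adopts the width of its assigned motif anchored at the slot start
(clipped at the promoter end). The shuffle mean is closely
approximated by the closed form S(d) = 2N(B−d)/B², which obeys the
conservation identity Σ_{d=0..B} S(d) = N(B+1)/B. The screen tests
the short-gap count (d ≤ 25) against Poisson(Σ_{d≤25} S(d)),
upper-tail, Bonferroni-corrected over the pairs tested; counts and
means are summed over species before a single test per pair. Using
the analytic mean for the Poisson rate keeps the genome-wide step
closed-form; the shuffle machinery remains available (`null_profile`)
and is validated against both the formula and exhaustive enumeration.

The spacing-*shape* step permutes labels within each promoter
independently, which holds each pair's total co-occurrence count fixed
when sites do not overlap; with overlapping sites the total can drift
by a few counts, so the chi-square comparison conditions on the
observed total (rescaling the null mass; mismatches beyond 10% raise).
Unit-gap bins are merged left-to-right until every expected bin holds
mass ≥ 5; df = bins − 1; no multiple-test correction is applied at
this stage, which refines pairs already called by the corrected
genome-wide test. A promoter whose only slots are the two planted
sites is invariant under this permutation, so the shape test draws its
power from the full multi-motif site annotation — fixtures for the
shape test include background motifs for this reason.

### Formula-vs-simulation comparisons

The 1000-shuffle mean conditions on the one realized site placement,
so its per-gap deviation from S(d) is dominated by that placement's
own Poisson-level noise (SD ≈ √S(d)), not by the shuffle-estimation
error — and single-gap counts have a visibly heavier-than-Gaussian
tail. Agreement checks therefore average the null mean over five
replicate genomes (2,000 promoters each, two motifs, uniform
placement) and require the average to sit within 3 single-genome SDs
of S(d) at every gap with S(d) ≥ 5: replicate averaging isolates a
systematic formula error, which would still trip the bound, while a
single genome's placement flukes no longer do.

## Orientation

Each co-occurrence is classified by the strand pattern of its
(upstream, downstream) sites: tandem-plus (+,+), tandem-minus (−,−),
convergent (+,−), divergent (−,+); motif identity is not part of the
class. Each class count is tested against Binomial(n, 1/4),
upper-tail exact, with the four p-values Bonferroni-multiplied; the
smallest corrected p names the preferred arrangement.
Reverse-complementing every promoter swaps the two tandem classes and
fixes the other two, which the tests assert.

## Corroboration

Expression coherence: pairwise Pearson correlations among joint
targets, computed over the ≥ 3 conditions where both genes are
observed (zero-variance or data-poor pairs are skipped, not
NaN-propagated), are compared to the PCC distributions of each motif's
solo targets (genes with sites for one motif and none for the other)
by one-sided Mann–Whitney tests; the verdict requires both p < 0.01.
scipy's exact/asymptotic switching handles small samples and ties.
Set overlap (ChIP colocalization, perturbation response) is a
hypergeometric upper tail; pathway enrichment tests each annotation
term touching the target set and Bonferroni-corrects by the number of
such terms. A pair counts as corroborated when at least one evidence
class is significant at 0.01.

## ChIP occupancy

Reads are assigned to promoters by their 5′ position (fragment
midpoints are unknowable from short single-end reads); a read landing
in overlapping promoters counts for each. Counts are normalized to
reads per million mapped (RPM); the enrichment ratio is
(IP RPM + ε)/(INPUT RPM + ε) with ε = 0.5 raw reads RPM-scaled, so
zero-count promoters stay finite; per-gene ratios are averaged over
replicates. Ratios are invariant to sequencing depth by construction.

The bundled peak caller slides a 300 bp window at 50 bp steps and
tests the IP count against Poisson(max(depth-scaled INPUT count,
genome-wide INPUT rate per window)), keeping windows with p < 1e-5 and
merging overlapping ones (minimum p retained); externally produced
peak BEDs are accepted wherever peaks are consumed. A gene is bound
when a peak overlaps its promoter in ≥ 2 replicates; joint targets are
genes bound by both TFs, and each single-TF set keeps its
best-p genes (gene id as tie-break) truncated to the joint-set size so
the three paired tests see equal sample sizes. Wild-type vs deletion
ratios are compared per gene set with a two-sided paired t-test
(default) or Wilcoxon signed-rank (exact for n ≤ 25 without zero
differences); identically zero differences return p = 1 by convention.

## Rewiring

Targets of a pair in each of two species (promoter carries the pair
within 25 bp) are mapped through a one-to-one ortholog table; genes
without an ortholog are excluded and counted, since the test compares
orthologs' expression. Sets A (species-1-only), B (shared), C
(species-2-only) must be disjoint. Relevant conditions per motif are
those where the motif's single-site targets deviate as a group: gene
values are standardized per condition and mean(target Z)·√n is tested
two-sided at 0.01 (≥ 5 observed targets required); a condition is kept
when relevant for either member of the pair.

The permutation test pools A and C and re-deals them into sets of the
original sizes 1,000 times; a re-deal succeeds when its A*-vs-B mean
PCC (species-1 data) and C*-vs-B mean PCC (species-2 data) both reach
the observed values (ties count as success, making p conservative);
p is the success fraction, add-one smoothed when zero. Mean PCC is
computed as the mean over X genes of each gene's mean correlation to
B — identical to the all-pairs mean under complete data and O(1) per
re-deal after precomputing per-gene vectors. Because success is a
*joint* event over two independent expression datasets, the success
fraction behaves like a product of two uniform tail probabilities
under an exchangeable null rather than a single uniform p-value: its
rejection rate at the 0.05 threshold is 0.05(1 − ln 0.05) ≈ 0.20, not
0.05. The statistic is reported as defined; users who need a
calibrated test should view p_rewire as a ranking score or threshold
it against an explicit null simulation, and the acceptance suite
records this property honestly.

## Synthetic fixtures

Generators emulate the study conditions: 600 bp promoters with
AT-rich yeast-like composition (0.31/0.19/0.19/0.31); planted pairs
use non-palindromic consensus words at gaps drawn from 0–25 bp with
configurable orientation probabilities, the A word upstream, and a
truth table for exact precision/recall; expression matrices give each
coherent set loading·latent + N(0, 1) with i.i.d. standard-normal
latents per condition (loading 0.8, 20–30 conditions by default);
ChIP counts are Poisson with 4-fold IP enrichment at bound promoters
and a constant, background-dominated library size (a library size
proportional to promoter counts would couple unrelated promoters
through RPM normalization). Every generator is deterministic under a
fixed seed.

What the fixtures do not emulate: nucleosome positioning and
accessibility, motif self-overlap and homotypic clustering, correlated
expression noise between conditions, mappability and duplicate-read
artifacts, and gene loss in the ortholog map. Passing tests therefore
demonstrate the statistics behave as designed under their own
assumptions, not that real genomes meet those assumptions.

## Problem sizes and defaults

Test and acceptance runs use sizes chosen to make the statistical
properties measurable while keeping the whole suite quick on a single
CPU: 2,000-promoter genomes (×5 replicates) for the formula check,
50 null replicates × 15 pairs for screen calibration, 20 replicates
with 60 planted promoters for recovery, 100 fixtures for the rewiring
null, and 1,000 permutations/shuffles wherever the method prescribes
1,000. Screen defaults — 600 bp promoters, 25-fold affinity cutoff,
25 bp interaction limit, α = 0.01 with Bonferroni over pairs, 1,000
shuffles — are the method's own study conditions, not tuning knobs.

## Known limitations

- The analytic S(d) ignores edge effects of order w/B (a few percent);
  at desk scales this is well inside placement noise, and the
  genome-wide Poisson step inherits that approximation.
- Overlapping site predictions make the promoter-level N only
  approximately invariant (the shape test conditions on the total).
- Within-promoter permutation has no power at promoters carrying only
  the pair's two sites.
- The rewiring p is anti-conservative as a fixed-level test (see
  above).
- The orientation classes fold out motif order; an order-aware 8-class
  decomposition is out of scope.
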