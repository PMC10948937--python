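# Methods

This note documents the statistical models, parameter choices and
numerical conventions behind `dmrflow`, and what the synthetic-data
tests do and do not establish about real data.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention); 1-based input
dialects must be converted at the reader boundary. Chromosome names are
kept verbatim; the canonical filter accepts autosomes `chr1`–`chr22`
(optionally `chrX`/`chrY`) and rejects scaffolds and `chrM`. Interval
sets iterate deterministically — chromosome (lexicographic), start, end,
insertion index — so every downstream table is reproducible.
`subset_by_overlap` requires the minimum overlap against a *single*
subject interval (not the summed overlap across subjects);
`intersect_spans` assigns each output fragment the metadata of its
contributing query interval.

## DMR calling

**Tiles (bisulfite counts).** Tiles with any sample under 10 reads, or
on non-canonical contigs, are removed before testing. Per tile, pooled
methylated/total counts per group are compared with a two-proportion
statistic whose variance is inflated by a method-of-moments
overdispersion factor φ = max(1, Pearson χ²/df) estimated across the
samples (df = n₁+n₂−2). Because φ is estimated, the statistic is
referred to a t distribution with n₁+n₂−2 degrees of freedom rather
than the normal; with 10-vs-10 samples at ~30× depth this keeps the
null p-values uniform (the test suite checks KS uniformity over 5,000
null tiles). BH correction runs across tiles; calls require q < 0.05
and |Δβ| ≥ 0.25, where Δβ is the difference of the groups' mean
per-sample methylation proportions. This caller is a deliberately
simple, replaceable stand-in for beta-binomial GLM machinery; the
filtering and harmonization rules around it are the point.

**Probes (array betas).** Probe-wise Welch t on beta values, optionally
after residualizing a categorical covariate (per-probe removal of
covariate-level means; skipped with a warning if the covariate exactly
reproduces the group partition). Probes with q < 0.05 and |Δβ| ≥ 0.05
are merged into regions while consecutive probes are ≤ 1,000 bp apart
(a strictly larger gap splits — the merge gap mirrors a common
kernel-smoothing bandwidth default and is exposed as a parameter).
Region Δβ is the mean of member-probe Δβ, region q the minimum member
q; regions are kept at |Δβ| ≥ 0.20. Kernel smoothing itself is out of
scope.

**Control filtering.** Main-comparison DMRs are intersected (per bp)
with the union of the control comparisons; only intersecting spans
survive, inheriting the main DMR's Δβ/q. No direction matching is
applied between main and control regions — the filter is purely
positional.

**Cancer-specific extraction.** Only DMRs with |Δβ| ≥ 0.25 enter. On
the array platform each member probe is extended by 500 bp per side and
carries its DMR's Δβ; extended probes from the two comparisons pair
when the overlap of a *pair* is ≥ 600 bp with matching direction, and
the merged pairwise intersections are returned (the most conservative
region satisfying both comparisons). On the tile platform, exact tile
identity with matching direction is required.

## Enrichment statistics

The contingency unit is a measurement unit (500-bp-extended probe or
tile). "Bound" means ≥ 1 bp overlap with any site of the TF — the
minimal-overlap choice is configurable, since no natural threshold
exists for catalog sites of heterogeneous width. One-sided
(enrichment) Fisher p-values come from the hypergeometric survival
function; BH families are all TFs within a single (target set,
category) run. Co-localization tests each unordered TF pair over the
target regions (both/only-first/only-second/neither) and adjusts over
the upper triangle before mirroring. Binding-site methylation summaries
take probes within 500 bp (inclusive) of a site and average per group.

## TAD-scale shifts

Thresholds are exact: majority-direction hits ≥ 5, opposite fraction
strictly < 1/10 (1 opposite in 10 fails, 1 in 11 passes), span of
qualifying units strictly > 50 kb, all per platform, both platforms
agreeing on direction. Flagged TADs from the five TAD sets are pooled
and merged per (comparison, direction). Two caveats are documented
rather than hidden: (i) the span and hit criteria are evaluated per
platform, both required — the source phrasing admits a joint reading;
(ii) raising the per-unit |Δβ| cutoff is *not* strictly monotone in the
number of flagged TADs, because a higher cutoff can prune the lone
opposite-direction hit that was failing the 1/10 rule.

## Developmental taxonomy

Similarity is decided purely from the presence/absence of called DMR
overlaps: no tumor-vs-PSC DMR but a tumor-vs-FB DMR ⇒ PSC-like; the
mirror ⇒ FB-like; overlaps against both references ⇒ unique; no
overlap anywhere ⇒ unique/unchanged (zero-evidence fallback).
"Similarly methylated" is thus operationalized as the absence of a
called DMR, not as a beta-distance band. The differentiation axis
follows the PSC-vs-FB flag, whose direction is stated w.r.t. PSC:
PSC-hyper ⇒ demethylated during differentiation. A comparison
overlapped by DMRs of both directions makes the atom `ambiguous`. The
mapping is total over the flag space and the full truth table is
enumerable via `category_truth_table()`; regions are first atomized at
every reference-DMR breakpoint, so atoms are disjoint and cover the
input footprint. Reference DMRs reuse the probe caller with |Δβ| ≥
0.25 and an inclusive 100–5,000 bp length filter.

## Methylation–expression integration

DE calling is a Welch t on log-scale expression (log2-CPM with a 0.5
prior for counts; intensities as given), BH per comparison;
significance needs adj. p below the preset (0.05 by default, 0.01 in
the `strict-results` preset) and |log2FC| ≥ 1 on *both* platforms with
agreeing sign. Multi-probe expression inputs are collapsed to genes by
the mean before testing. Promoters are transcript-level (2 kb up, 500
bp down, strand-aware, clipped at 0); enhancer links from
curated-catalog sources require confidence ≥ 5; neighborhoods span
±200 kb around the TSS. Cross-platform validation requires a
same-direction DMR linked to the same gene within 5 kb (inclusive) on
the other platform. The TAD-boundary screen takes the span from the
TSS to the DMR edge nearest it; a boundary is a TAD start or end
strictly inside the open span (touching an endpoint does not count),
and in the default literal mode a gene is dropped if *any* of its pairs
crosses a boundary in *any* TAD set (an `any_clean` mode retains genes
with at least one clean pair). Classification per (gene, comparison):
`opposite` (the DM-DE call) when all supporting DMR links have sign
opposite to the expression change, `parallel` when all agree, `mixed`
(excluded) otherwise. The orchestrated pipeline links through promoters
and enhancers; neighborhood linking is available but not part of the
default DM-DE call, since a ±200 kb window around a recurrently
methylated locus routinely sweeps in unrelated DMRs whose directions
would force spurious `mixed` labels.

## CUT&RUN filtering and motif scanning

Replicates are unified by bp-intersection (the conservative reading of
"called in both replicates"); control subtraction drops a peak on ≥ 1
bp overlap; the canonical filter removes chrX/chrY and scaffolds.
Motif scanning discretizes the log-odds matrix to 1e-3 bins (floor) and
computes the exact distribution of window scores under a zero-order
background by dynamic programming; the hit threshold is the smallest
achievable score with tail probability < 0.001. The scanner sums the
same discretized per-position scores, so hit decisions are exact w.r.t.
the discretization (error ≤ width·1e-3 log2-units); `N` bases score 0
(background vs background). Both strands are scanned. The background
defaults to uniform; a sequence-derived zero-order background can be
supplied through the `PWM` constructor.

## Synthetic study

The generator emulates the statistical structure of a multi-cohort
tumor methylome study, not its genome: four 5-Mb autosomes (plus a
small chrX and a scaffold to exercise the canonical filters), 1-kb
tiles covering the autosomes, 50-bp probes in ~70% of tiles (four per
tile inside planted regions). Groups: 10 samples per tumor type, 8
controls, 6 PSC, 6 FB. Unit methylation is Beta(μc, (1−μ)c) with
concentration c = 60 (SD ≈ 0.064 at μ = 0.5, matching overdispersed
bounded methylation data); tile totals are Poisson(30)+1 with
methylated counts Binomial(total, β); a handful of tiles are forced
under the coverage threshold to exercise filtering.

Planted signals: 39 cancer-specific DMRs (hyper-biased in the
AT/RT-like group, hypo-biased in MB/PLEX-like) with Δβ = 0.4 against
every other group, each assigned one of four developmental-offset
patterns realized through the PSC/FB group means; four TAD-scale
clusters of single-tile DMRs spread over > 50 kb (one with only four
units as a deliberate near-miss); one TF with half its sites inside the
AT/RT-hyper class (≈ 5× background) and one enriched only through a
single catalog category; 12 opposite-direction (DM-DE) and 6 parallel
expression genes at |log2FC| = 2 on both expression platforms (n = 8
per group), linked through promoters or enhancers; and CUT&RUN peak
sets with known replicate/control/evidence structure, the MB-like
sample dominating as in the real assay. Each planted region occupies
its own TAD grid slot so ordinary regions cannot aggregate into
accidental large-scale clusters. Hypo-direction regions flip the
PSC-vs-FB contrast, so recorded truth categories flip the
differentiation half of the label accordingly.

What passing these tests shows — and does not. Recovery at these
effect sizes and sample counts demonstrates that every rule and
threshold is implemented as specified and that the callers are
calibrated under the generator's beta-binomial noise; it does not
demonstrate power or FDR control on real cohorts, where probe-level
covariance, batch structure, copy-number artifacts and annotation error
are all absent from the simulation. Problem sizes (20,090 tiles,
~14,300 probes, 15-TF catalog) were chosen so a full run completes in
seconds while leaving every statistic in a regime where its asymptotics
are honest.

## Model selection for clustering

k-means uses Lloyd iterations with uniform random row initialization
(best of 50 starts, 25 iterations, seeded); AIC(k) = WSS(k) + 2·k·d
with d the feature count — a standard heuristic form, exposed as a
pluggable criterion since no canonical k-means AIC exists. Missing
betas are row-mean imputed before clustering. The chosen k on real
data therefore depends on this AIC form and is not guaranteed to match
any particular published cluster count.

## Degenerate inputs and numerical conventions

Zero-variance rows give p = 1 (not NaN). Beta values are clipped to
[1e-4, 1−1e-4] at generation to keep Beta draws valid at extreme means.
Empty DMR/control/peak sets return empty results with warnings rather
than errors wherever the operation has a sensible vacuous answer; fully
confounded covariates are skipped with a warning. BH adjustment
preserves input order; ties in variance ranking break by genomic order;
all randomized procedures take explicit seeds.
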