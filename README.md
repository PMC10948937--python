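# dmrflow

Cross-platform differential DNA-methylation analysis for tumor
methylome comparisons, built around the analytical flow used to
characterize atypical teratoid/rhabdoid tumors (AT/RT) against
medulloblastoma (MB) and choroid plexus tumors (PLEX): DMR calling on
two measurement platforms, harmonization of the results, transcription
factor (TF) binding-site enrichment, TAD-scale methylation shifts,
developmental categorization against stem-cell and fetal-brain
references, methylation–expression integration, and CUT&RUN peak
filtering.

The package is aimed at computational epigenomics researchers who want
a tested, fully synthetic-data-driven reimplementation of this kind of
multi-stage pipeline: every stage can be exercised end-to-end on a
generated study with planted ground truth, so each rule (overlap
windows, thresholds, direction handling) is verifiable.

## What it computes

**Methylation model.** A unit (array probe or 1-kb sequencing tile)
carries a methylation level β ∈ [0, 1] per sample. Differential
methylation between groups is summarized as Δβ (difference of group
means), tested per unit and corrected with Benjamini–Hochberg; a DMR is
a run of significant, same-direction units with |Δβ| above a platform
threshold (0.20 for merged array regions, 0.25 for 1-kb tiles,
q < 0.05). The tile test is a two-proportion statistic on pooled
read counts with a method-of-moments overdispersion factor
φ = max(1, Pearson χ²/df); the array test is a probe-wise Welch t.

**Harmonization.** Array DMRs are filtered by intersection with
normal-control comparisons; cancer-specific regions are those
differential in the same direction against *both* other tumor types —
with ≥ 600 bp overlap between the comparisons' 500-bp-extended probes on
the array platform, and exact tile identity on the sequencing platform.

**Enrichment.** For a TF with binding-site catalog S, enrichment of S in
target units T against a unit background B is a one-sided Fisher exact
test on the 2×2 table (bound/unbound × in-T/not-in-T), BH-corrected per
run, optionally per sample-type category of the catalog, and validated
across platforms by intersection of significant TFs.

**Large-scale shifts.** A TAD is flagged when, on each platform, ≥ 5
same-direction units with |Δβ| ≥ 0.25 fall in it, opposite-direction
hits are < 1/10 of hits, and the units span > 50 kb.

**Developmental categories.** Cancer-specific regions are atomized
against seven reference comparisons (each tumor vs pluripotent stem
cells [PSC] and fetal brain [FB], plus PSC vs FB) and labeled on two
axes: similarity (PSC-like / FB-like / unique, from the
presence/absence of called DMR overlaps) and differentiation behavior
(de-/methylated during PSC→FB differentiation / unchanged).

**DM-DE genes.** Genes differentially expressed on both expression
platforms (|log2FC| ≥ 1, BH-adjusted p below the preset) whose linked
regulatory region (transcript promoter = 2 kb upstream/500 bp
downstream of the TSS; enhancer with confidence ≥ 5; or ±200 kb TSS
neighborhood) carries a cross-platform-validated DMR (same direction
within 5 kb on the other platform, no TAD boundary between TSS and DMR)
of *opposite* direction to the expression change.

**CUT&RUN.** Peak sets are reduced to the bp-intersection of
replicates, cleared of control-overlapping and non-canonical-chromosome
peaks, and retained when they overlap a binding-site catalog or contain
the TF's motif at p < 0.001 — the motif threshold comes from an exact
dynamic program over the discretized log-odds score distribution.

## Worked example

Generate the default synthetic study (three tumor groups of 10 samples,
8 controls, 6 PSC and 6 FB methylomes over a 4×5-Mb genome with 64
planted DMRs) and call tile DMRs for the AT/RT-like vs MB-like
comparison:

```python
from dmrflow.synthetic_data import StudyConfig, generate_study
from dmrflow.dmr_pipeline import call_dmrs_tiles

study = generate_study(StudyConfig(), seed=1)
dmrs = call_dmrs_tiles(study.tiles, "ATRT", "MB")
print("n DMRs:", len(dmrs))
print(dmrs.df.head(3)[["chrom", "start", "end", "delta_beta", "q", "direction"]])
```

prints

```
n DMRs: 79
  chrom    start      end  delta_beta         q direction
0  chr1   443000   444000    0.386533  0.000018     hyper
1  chr1   444000   445000    0.408148  0.000049     hyper
2  chr1  1077000  1078000    0.396875  0.000042     hyper
```

79 single-tile DMRs at q < 0.05 and |Δβ| ≥ 0.25; the first three are
hypermethylated in the AT/RT-like group with estimated Δβ ≈ 0.39–0.41,
matching the planted effect of 0.4.

The full pipeline runs from the shell:

```sh
dmrflow all --seed 1 --outdir out/
```

which writes per-stage tables (DMR BEDs, enrichment TSVs, the
developmental matrix, DM-DE genes, CUT&RUN summaries) and
`out/recovery_report.json` comparing every stage's output with the
planted truth (DMR sensitivity/FDR, the planted TF's rank, TAD cluster
recovery, category label agreement, DM-DE gene recovery, and the
uniformity of the test's p-values on the study's null tiles).

## Layout

| module | role |
| --- | --- |
| `dmrflow.genomic_core` | 0-based half-open interval algebra, BED I/O |
| `dmrflow.containers` | BetaMatrix / TileCounts / DMRSet containers |
| `dmrflow.synthetic_data` | synthetic study generator with planted truth |
| `dmrflow.dmr_pipeline` | two-platform DMR calling and harmonization |
| `dmrflow.methylation_stats` | k-means+AIC, Wilcoxon, Cliff's δ, BH |
| `dmrflow.tfbs_enrichment` | Fisher enrichment, categories, co-localization |
| `dmrflow.tad_analysis` | TAD-scale shift detection |
| `dmrflow.developmental_context` | PSC/FB reference categorization |
| `dmrflow.dmde_integration` | DE calling and DM-DE classification |
| `dmrflow.cutrun_filter` | peak filtering and PWM motif scanning |
| `dmrflow.pipeline`, `dmrflow.cli` | orchestration and the `dmrflow` CLI |

Extended-BED dialect: DMR files carry
`chrom start end name(=comparison) score(=round(Δβ·1000)) strand q
direction n_units platform` columns; plain BED files written by
`genomic_core.write_bed` add declared meta columns after a `#` header
line. See `docs/methods.md` for the scientific and numerical details.
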