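# Methods

## The measurement problem

Embryos inherit a pool of maternally deposited mRNA; their own genome
activates during the maternal-to-zygotic transition (MZT). Because maternal
deposition is identical for female and male embryos, sex differences in
transcript abundance are informative only for zygotic transcription — and in
a cross between genetically distinct parental lines, reads overlapping fixed
SNPs can be assigned to the maternal or paternal allele, separating the two
transcript sources directly. All analyses in this package are built on that
separation.

Stages are stored as ordinals 1..8; the morphological labels
(2, 4, mid-5, late-5, 7, 8/9, 10, 12) are display metadata, because species
develop at different rates and samples are matched by morphology, not clock
time. Coordinates are 0-based half-open throughout (GFF input is converted
on read). Missing allele data (a gene without informative SNPs) is
represented by absent rows, never zero counts: absence of SNPs is not
absence of transcription.

## Normalization

Each sample is scaled so its summed RPKM over the reference autosomes
(chromosomes 2 and 4, autosomal in every profile) equals a common target
`T_ref` (default: the across-sample mean). The scale factor is retained on
the expression table so allele-level read quantities can be placed on the
same per-sample scale. Alternative modes (all autosomes; no rescaling) are
provided; the X-to-autosome contrasts the package computes are insensitive
to the choice.

## Zygotic-fraction estimator

For gene *g* in sample *j*, maternal and paternal reads are summed over SNPs
and divided by the number of SNPs observed (SNPs with at least one read;
unobserved SNPs carry no information). The paternal fraction
*p* = pat/(mat+pat) is undefined — not zero — when no allele reads were
seen. Assuming biallelically balanced zygotic transcription, *ẑ* = 2*p*
estimates the zygotic share; it is clipped to [0, 1] because sampling noise
can push 2*p* above 1 while a transcript fraction cannot. Doubling is
applied per gene/sample and then averaged across replicate embryos (the
embryo is the unit of replication); a flag selects the alternative
average-then-double order. X-linked estimates use female embryos only, since
males carry no paternal X.

Clipping makes *ẑ* slightly conservative for genes that are almost purely
zygotic; at the default read depth the net bias of the stage-level mean is
under 0.01 (measured against generator truth in the test suite).

## Zygotic gene classification

Two definitions, each per species:

* **allele-specific** (per stage): female mean RPKM > 5 and female paternal
  fraction > 0.40. Stage- and species-specific; genes without allele data
  are *not callable*, which is distinct from a negative call.
* **transcript-level** (per gene): mean RPKM < 5 at the first sampled stage
  (no maternal deposition) and > 5 at one or more later stages. A
  `sustained` flag requires all stages after the first crossing to stay
  above the floor.

Thresholds are strict inequalities. Replicates are averaged before
thresholding. The allele-specific definition conditions on allele data and
is used for total-transcript-level analyses (sex-bias ratios); the
transcript-level definition is used for allele-level analyses (maternal
allele onset) to avoid conditioning an allele-specific result on an
allele-specific call.

## Sex-bias ratios and classes

Per stage, *r* = mean♀/mean♂ RPKM for genes whose means exceed 5 RPKM in
both sexes (which also removes zero denominators, so no pseudocounts are
used) and that are zygotic under the supplied calls. Class cut points
default to {0.8, 1.25, 1.5, 2.0}: the 1.5 and 2.0 boundaries anchor the
female-bias cutoff comparisons and the compensated/uncompensated split; the
intermediate boundaries are package defaults and fully configurable, since
no canonical values exist for them. Chi-squared cutoff comparisons use a
2x2 table (above/below cutoff x group), df = 1, no continuity correction by
default (a Yates flag exists), over a cutoff grid 1.5–2.0 in 0.1 steps,
reported unadjusted with a Benjamini–Hochberg column for completeness.
Wilcoxon rank-sum tests are two-sided, exact when both groups have at most
10 untied observations, normal approximation with tie correction otherwise.

## Bootstrap inference

Genes — not embryos — are the resampling unit everywhere. A 95% interval is
the empirical 2.5%/97.5% quantiles of the statistic over `n_boot` (default
1000) resamples with replacement, deterministic given a seed. The onset
detector flags a (stage, chromosome-class) cell when the male maternal-allele
mean exceeds the female 97.5% quantile; this one-sided CI-exclusion rule is
the operational definition of significance, and no additional p-value is
invented. Because male and female means are computed over the *same* genes,
between-gene level variance is common to both sexes and the rule is
conservative in practice: under a no-compensation null the measured
false-flag rate is far below the nominal 2.5% per cell. Cells with fewer
than 10 zygotic genes are flagged low-power and excluded from onset
determination. Maternal-allele levels are per-SNP read counts scaled by the
sample's normalization factor, making male and female samples comparable;
an RPKM-share alternative would change units but not the male:female ratio
that the detector thresholds.

The stage-correspondence analysis computes Spearman correlations between
per-stage mean expression vectors of two timecourses over shared
(orthologous) genes, a gene-resampling CI for each same-stage correlation,
and a row p-value: the fraction of bootstrap replicates in which the row's
best off-diagonal correlation beats the diagonal.

## Neo-XY analyses

Male reads at neo-divergence SNPs split into neo-X (maternal in males) and
neo-Y (paternal) components. Genes without neo-divergence SNPs cannot be
partitioned but keep their combined totals, so combined neo-XY analyses
retain them. ORF-stratified sex bias is computed in two modes: combined
(male denominator includes retained neo-Y transcription) and neo-X-only
(male mean multiplied into its neo-X read share), with Wilcoxon comparisons
between intact and broken strata and against the older X arms.

## Spatial and chromatin tests

The clustering statistic is the mean distance from each labeled gene to its
nearest same-labeled neighbour; gene position is the start coordinate
(midpoint by flag). The null resamples equally many genes *without*
replacement — a gene set, not a bootstrap — from the zygotic genes of that
stage, because zygotic genes are themselves spatially clustered and a null
drawn from all genes would mistake zygotic clustering for
compensation-specific clustering (both universes are supported so the
contrast can be demonstrated). Empirical p-values use the add-one
convention p = (1 + #{null ≤ obs})/(n_reps + 1), so p is never zero. HAS
proximity uses the minimum distance from gene start to any high-affinity
site interval (0 inside), pooled across chromosomes by default; genes in
the lower quartile of distances (ties included) are compared to the rest by
Wilcoxon on their F:M ratios. H4K16ac comparisons bootstrap the mean
enrichment of compensated (r < 1.5) vs uncompensated (r > 1.5) genes with
exclusion flags in both directions.

## The synthetic-data generator

The generator emulates the experimental design the analyses assume: 8
morphological stages x 2 sexes x 3 replicate single embryos, chromosomes
{2, 4, XL, XR, 3}, with chromosome 3 autosomal in `pse_like`/`mel_like` and
the neo-XY pair in `mir_like`.

Per gene: a maternal deposition level (present with probability 0.6,
log-normal with median 20 RPKM, log-sd 0.8) decaying geometrically at
0.35/stage after the MZT stage (ordinal 3); a zygotic flag (probability
0.5) with per-copy rate (log-normal, median 25 RPKM, log-sd 0.8) and an
onset stage drawn from a distribution concentrated at the MZT. The per-copy
zygotic median sits well above the 5 RPKM analysis floor so that the
inclusion rule does not differentially truncate hemizygous male levels —
the regime in which the sex-ratio analyses operate on real data, where
uncompensated X ratios measured under the same rule sit near the 2-fold
dose. Male X zygotic transcription is multiplied by a non-decreasing
per-stage compensation factor in [1, 2]: identically 1 before the ramp,
reaching 2 by the final stage (`pse_like` ramps over ordinals 5–7;
`mir_like` applies a one-stage species delay to both zygotic onset and the
ramp; `mel_like` gives exactly half of zygotic X genes factor 2 from
activation — early partial compensation). Neo-Y copies are transcribed at a
per-gene retention fraction of the neo-X rate (30% silenced, the rest
Beta(2,2)), drawn independently of ORF status (half intact, half broken),
mirroring the observed independence of neo-Y decay and neo-X compensation.

Counts are gamma-Poisson (negative binomial) with size 20 by default —
chosen to reproduce the high replicate-to-replicate rank correlation
characteristic of single-embryo mRNA-seq — with a Poisson option. RPKM is
derived from simulated counts at a fixed 1 kb gene length and a fixed
reads-per-RPKM constant, keeping the count-to-RPKM mapping transparent.
SNP-overlapping reads are drawn with mean proportional to expression (200
reads for a gene at the reference 20 RPKM level) and split
maternal:paternal binomially according to the transcript pool's
composition; male X genes therefore have exactly zero paternal reads, and
male neo-XY genes additionally split neo-X:neo-Y at separate
neo-divergence SNPs (68% of neo genes). SNP informativeness is 92%
(`pse_like`/`mel_like`) or 75% (`mir_like`) of genes.

What the generator does **not** emulate: read-level effects (mapping bias,
positional coverage), true gene-length variation, correlated expression
programs between neighbouring genes (an optional clustering knob places
zygotic genes in clusters for the spatial null demonstration, but there is
no co-expression), cross-species divergence in per-gene levels (a second
"species" reuses the same per-gene parameter table), or embryo staging
error. Passing recovery tests therefore demonstrates the statistical
machinery is calibrated and unbiased under the assumed data-generating
structure — not robustness to alignment artifacts or annotation error in
real data.

## Problem sizes and numerical choices

Default simulations are 1,800 genes x 48 embryos, which the package
processes in about a second; the onset-detection calibration suites use 100
recovery and 200 null simulations of a 1,400-gene experiment, and bootstrap
coverage is measured over 1,000 simulations at n = 100 with 1,000
resamples — sizes chosen to make Monte-Carlo error small relative to the
tolerances being checked. Ratios are never formed with pseudocounts;
undefined quantities propagate as missing values, and degenerate cells
(one-gene classes, single-sex stages, empty strata) are flagged or skipped
with warnings rather than silently dropped. Quantile-based intervals are
widened, when necessary, to include the full-sample point estimate so that
degenerate tiny-sample resamples cannot produce an interval excluding its
own estimate.

## Known limitations

The allele-specific zygotic definition cannot call genes lacking SNP
coverage, so per-stage zygotic sets are biased toward SNP-dense genes; the
transcript-level definition misses genes with both deposition and zygotic
transcription. The onset detector reports the earliest *detectable* stage,
which lags the true onset when the compensation ramp is shallow relative to
between-gene variance. The clustering and HAS tests treat gene positions as
exchangeable within a chromosome and ignore recombination or domain
structure.
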