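# Methods

`cnvgwas` implements a complete copy-number-variant (CNV) association
workflow for SNP-array cohorts: Log R Ratio (LRR) preprocessing, joint
multi-sample segmentation, common-CNV calling, PCA-corrected permutation
association against estimated breeding values (EBVs), interval annotation,
and qPCR validation arithmetic. This note records the models, the defaults
and why, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Signal model and preprocessing

The LRR of a marker is log2(observed / expected intensity); a hemizygous
deletion shifts it down by roughly 0.5–0.6 and a single-copy duplication up
by roughly 0.4. Two artifacts are handled before segmentation:

* **Missing entries** are mean-imputed per marker (segmentation needs a
  dense matrix); the imputed count is logged. Markers missing everywhere
  fall back to the LRR baseline of 0.
* **GC waviness** — the long-range correlation between LRR and regional GC
  fraction — is removed per sample by least squares of LRR on the marker
  map's `gc_fraction`, subtracting `b·(gc − mean gc)`. The slope is fit
  with one outlier-trimming pass (markers beyond 3 robust SDs of the
  first-pass residuals are dropped and the slope refit): copy-number
  shifts are gross outliers relative to LRR noise, and left in the fit
  they bias the slope whenever an event sits in a GC-skewed region —
  on small simulated genomes, where events are several percent of all
  markers, an untrimmed slope visibly overcorrects and can mask true
  breakpoints. The subtraction preserves each sample's mean LRR exactly
  and is idempotent to 1e−8. Vendor GC-correction files use unpublished
  windowed algorithms; a single global regression per sample is the
  simplest model consistent with a GC-linear artifact, and it removes the
  generator's shared wave to |r| < 0.05. A rolling-window variant is
  deliberately out of scope.

Only autosomal markers are analyzed; the restriction step reports the
retained count and percentage.

## Joint segmentation

Commercial "multivariate" CNV segmentation is proprietary. We use greedy
recursive binary splitting on the pooled (all-samples) within-segment sum
of squares, with the three published constraints as acceptance rules for a
candidate breakpoint:

1. both children have at least `min_markers` markers (default 3);
2. a paired t-test across samples on the per-sample difference of the two
   children's segment means has p ≤ `max_pairwise_p` (default 0.005) —
   pairing matters: in an unpaired test the carriers of a low-frequency
   event inflate the across-sample variance of the flanking means and
   mask the very boundary being tested, whereas the paired differences
   isolate the within-sample step;
3. the chromosome's segment count stays within the budget of
   `max_segments_per_10k_markers` (default 20) per started 10k-marker
   window, i.e. `20·ceil(n/10000)` segments.

Candidates across all active segments are processed in order of decreasing
SSE reduction (ties to the leftmost breakpoint, for determinism); a
rejected candidate finalizes its segment. The budget is read as a density
cap: scaling it per started window rather than strictly proportionally
keeps small chromosomes segmentable (a strictly proportional cap would
allow only one segment per 5k markers, which makes the method useless on
short chromosomes and on desk-scale benchmarks). The pairwise rule is
applied to adjacent segments only.

On the reference benchmark (50 samples, 200 markers, one 10-marker loss of
shift −1.0 at 30 % carrier frequency, noise sd 0.15) the splitter recovers
both breakpoints within ±1 marker with recall ≥ 0.95 and precision ≥ 0.90
over 20 seeds, and on ≤ 60-marker chromosomes it attains within 1 % of the
exhaustive two-breakpoint SSE optimum.

**State calls.** Each (sample, segment) pair is called from its mean
corrected LRR with the inclusive rule: mean ≤ −0.4 → loss, mean ≥ +0.4 →
gain, else neutral. The threshold is inclusive on both sides ("±0.4"
leaves the boundary undefined; inclusive is deterministic and documented).
Per-sample means, not the cohort mean, are thresholded — per-sample
genotypes require it.

## CNV events, filtering, naming, genotypes

Segments variant in at least one sample are merged per chromosome when
they overlap in basepairs or are bookended (adjacent marker ranges),
producing pairwise non-overlapping events spanning the union. A sample
carrying both loss and gain among an event's constituent segments gets the
state of the longer span, ties going to loss; every application of this
invented rule is logged. Loss and gain at the same locus form one event
with per-sample states rather than two events.

Filtering is two-step, in order: events variant in fewer than
`min_carrier_samples` samples (default 10; loss and gain pooled) are
dropped first, then events longer than `max_length_bp` (default 5 Mb).
Retained events are named CNV1…CNVn by descending loss frequency (ties by
chromosome then start) and coded additively: loss = 0, neutral = 1,
gain = 2. Event coordinates are boundary-marker positions, not midpoints
between flanking markers.

## Association model

For one trait, samples are gated by EBV accuracy strictly greater than
`min_accuracy` (default 0.50) with non-missing EBV. Each event j is
tested separately in

    y_i = a + Σ_c γ_c PC_ic + x_ij β_j + e_i,

where the top `k_pcs` (default 10) principal components of the
centered, unit-scaled CNV genotype matrix absorb population
stratification. A joint regression over all events simultaneously is
unidentifiable when the event count approaches the sample count, so the
additive model's summation is realized as the standard one-predictor-
per-test genome scan. PCs come from the CNV genotypes themselves, keeping
the pipeline self-contained (no SNP genotypes are required).

Significance uses **Freedman–Lane permutations** (default 10,000): y is
residualized on [1, PCs], the residuals are permuted with a seeded
generator, added back to the covariate fit, and the full-model
t-statistic for x_j is recomputed; the two-sided p-value is
(1 + #{|t*| ≥ |t|}) / (1 + B), so p ≥ 1/(B+1) and never 0. The same
permutation stream serves every event, which is what makes the scan
vectorizable: by Frisch–Waugh the full-model t depends only on the
correlation between covariate-residualized x_j and the re-residualized
permuted residuals, so each permutation block is two matrix products.
Asymptotic t-distribution p-values are emitted alongside as a diagnostic
column. Per trait, permutation p-values are Benjamini–Hochberg adjusted
across events (not pooled across traits) and events with q < `alpha`
(default 0.05) are flagged significant. With a fixed seed the fit is
bit-reproducible.

Zero-variance or covariate-collinear genotype columns yield flagged
records with missing statistics; collinearity among the covariates
themselves is a hard error naming the offending columns.

Calibration at study settings: with 200 independent null events, n = 500
and 2,000 permutations, the raw rejection rate at 0.05 sits inside the
central 95 % interval of Binomial(200, 0.05); a planted β = 0.8 at 30 %
carrier frequency is recovered as significant with β̂ ∈ [0.6, 1.0]; and
two-subpopulation confounding (offset 1.0, frequency shift 0.3) inflates
the uncorrected null rate to ≈ 0.24 while k = 10 PCs restore ≈ 0.05.

## Annotation rules

Intervals are 1-based inclusive; overlap_bp = min(ends) − max(starts) + 1.
Gene overlap requires ≥ 1 bp. Geometry: a gene fully inside the event is
`gene-within-cnv`; otherwise touching any exon is `exon-overlap`; an event
inside the gene body touching no exon is `intron-contained`; anything else
`partial` (containment is classified before the exon test, since a
contained gene's exons always intersect). Promoter scanning uses the
strand-aware window [TSS − 2000, TSS − 1] (mirrored on −, clipped at
position 1). QTL records whose span exceeds 30 Mb are discarded before
overlap; a hit requires a **single** QTL to cover ≥ 50 % of the event's
length — coverage is per-QTL, never unioned across QTLs. Searches are a
sorted sweep per chromosome; at hundreds of events and thousands of track
records no interval tree is warranted. genePred input is 0-based
half-open on disk and converted on read; all decisions are invariant to
BED round-tripping and to track order.

## qPCR arithmetic

Relative quantity follows the plain Livak method with efficiency fixed at
2.0: replicate CTs are averaged first, ΔCT = CT(target) − CT(control),
ΔΔCT subtracts the reference sample's ΔCT, RQ = 2^−ΔΔCT. Integer copies =
round(RQ · 2) with half-up rounding (the rounding rule is a documented
choice). Concordance between array states and qPCR calls is the fraction
of (sample, target) pairs agreeing after mapping copies < 2/= 2/> 2 to
loss/neutral/gain, computed per pair after triplicate averaging (not per
reaction). Copy-group expression comparison is one-way fixed-effects
ANOVA (for two groups F = t² exactly).

## Synthetic data: what it does and does not emulate

The generators are pure functions of their arguments including the seed.

* **Marker map**: exponential spacings (mean 10 kb scale), GC =
  0.5 + 0.25·sin(2π·pos/period + φ) + N(0, 0.02), clipped to [0.2, 0.8].
  The 0.25 amplitude gives real-array-like GC spread (≈ 0.25–0.75) and
  makes a 0.3-amplitude LRR wave clearly detectable above noise.
* **LRR**: i.i.d. N(0, noise_sd) per entry, optional AR(1) along markers
  for robustness tests; planted carriers get the event's shift over its
  markers; all samples share the GC wave term. Realistic shifts are
  ≈ −0.55 (one copy) and ≈ +0.4 (three copies); clean benchmarks use ±1.0.
* **Traits**: multivariate normal with the requested correlation matrix
  (unit variances), plus β·dose for planted effects, plus per-subpopulation
  offsets; accuracies are uniform and independent of values, since
  accuracy only gates inclusion.
* **qPCR**: expected CT = base(target) − log2(copies/2), Gaussian
  replicate noise, a dedicated diploid reference sample and a diploid
  control gene. At replicate noise sd 0.2 the implied ΔΔCT noise is
  ≈ 0.23 cycles, which predicts (and the benchmark confirms) ≈ 0.9
  copy-call concordance.

Not emulated: B-allele frequencies, probe-level intensities, LRR
autocorrelation by default, genomic waves beyond a single GC-linear term,
linkage between events, pedigree structure behind the EBVs, or
EBV-accuracy heteroskedasticity. Passing benchmarks therefore demonstrate
the pipeline's correctness and calibration under its stated noise model —
not detection power on any particular real array.

## Problem sizes and reproducibility

The reference benchmarks run on one CPU in well under a minute each:
segmentation recovery uses 20 seeds of 50 × 200; association calibration
uses 200 events × 500 samples × 2,000 permutations; stratification uses
10 paired seeds at 1,000 permutations; qPCR concordance uses 50 seeds of
the 5-target × 9-sample design. `scripts/acceptance.py` recomputes all of
them from scratch for a given `--seed` and finishes in seconds. Every
randomized routine takes an explicit seed; end-to-end pipeline reruns with
the same config and seed are byte-identical in their association and
annotation outputs.

## Known limitations

* The segmentation is a published-constraint approximation of an
  unpublished vendor algorithm; agreement with that vendor's output on
  real data cannot be asserted.
* Adjacent-only pairwise testing means a chain of slowly drifting
  segments is never compared end-to-end.
* Per-sample GC regression cannot remove GC effects that are nonlinear or
  sample-specific in shape.
* The association model assumes additivity in copy dose and homoskedastic
  residuals; EBV shrinkage correlations between relatives are ignored
  (no mixed model / genomic relationship matrix).
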