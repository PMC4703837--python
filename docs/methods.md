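# Methods

This note documents the statistical models, the numeric choices behind every
threshold, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the underlying procedure left room.

## The classification model

A chromatin feature at a genomic region is classified from four ChIP samples
at the α-amanitin comparison stage (stage 11) — control and
transcription-blocked, two biological replicates each — plus a reference-stage
sample (stage 10.5 for H3K4me3 and p300, stage 12 for H3K27me3).

**Quantification.** All samples are quantified on a merged peak set (union of
per-sample peak calls with overlapping or bookended intervals coalesced), so
that a region absent from one sample's calls is still measured there.
Enrichment is expressed as *relative RPKM*: RPKM divided by the
95th-percentile RPKM of random background regions of the same sample.
Background regions (default 10,000 when sampled; a generated table in the
synthetic pipeline) have widths resampled from the peak-width distribution;
the percentile is nearest-rank (the ⌈0.95·n⌉-th order statistic) to avoid
interpolation dialects. Relative RPKM is invariant under uniform scaling of a
sample's counts, so sequencing depth cancels.

**Filters.** Peaks with ≥75 % of their length in 1-kb input bins carrying
more than 65 input reads are excluded (copy-number and mapping artifacts; a
bin with exactly 65 reads does not count). Peaks not exceeding background
(relative RPKM ≤ 1) are excluded; a `literal_mode` switch applies the
opposite direction for comparison, because the two readings of the published
filter sentence conflict and only this one is consistent with the downstream
"rel. RPKM > 1" retention rules.

**Differential model.** For a control/treated count pair (x, y),
M = log₂((x+c)/(y+c)) and A = ½·log₂((x+c)(y+c)) with pseudocount c = 0.5.
The normalization assumption is that *common* peaks — detected in both
samples — are unchanged on average: a robust line M = a + b·A is fitted over
common peaks (iteratively reweighted least squares with the Tukey bisquare
loss, tuning constant 4.685, at most 50 iterations, tolerance 1e-8, started
from a Theil–Sen fit so that a leveraged outlier cloud cannot anchor the
iterations; plain Theil–Sen below 50 common peaks) and subtracted from every
peak's M. Detection, standing in for per-sample peak calling, requires a
count above the 99.9 % Poisson quantile of the expected background count at
the region's width *and* at least 4-fold that expectation.

**Significance.** The count statistic is the Audic–Claverie posterior
P(y│x) = (x+y)!/(x!·y!·2^(x+y+1)), i.e. y│x ~ NegativeBinomial(x+1, ½).
One-sided tails are evaluated in log space (via the regularized incomplete
beta function); the tail direction follows the sign of the normalized M, and
the statistic is applied to the normalization-rescaled counts rounded to
non-negative integers. No multiple-testing correction is applied — the
operating point thresholds the raw −log₁₀ p, and all calibration is at that
scale.

**Calls.** Per replicate: *lost* requires M > 1, −log₁₀ p above the per-mark
cutoff (5 for H3K27me3, whose broad domains produce large counts; 1.3 for
H3K4me3 and p300), and relative RPKM > 1 in the stage-11 control and at the
reference stage. *Increased* is the mirror image with treated-sample
enrichment. *Maintained* = not lost and enriched in control, treated and
reference samples; *unchanged* additionally excludes increased. The stage-11
control requirement can be waived per (mark, replicate) — the published
analysis waived it for H3K27me3 replicate 1 — and every waiver is explicit in
the configuration. Consensus: **MaD** = present at or before stage 11 and
maintained in both replicates; **ZyD** = present at or before stage 11 and
lost in both replicates, or first appearing after stage 11; otherwise **ND**.
Raising the M cutoff can only shrink the lost set, never create one
(monotonicity), and every peak receives exactly one consensus label.

**Gene level.** H3K4me3: the consensus label of peaks in the strand-aware
±250 bp promoter window; conflicting definitive labels give ND (logged), no
peak gives "unmarked". H3K27me3: ±2.5 kb window, one MaD peak suffices (MaD
dominates), ZyD requires a ZyD peak and no MaD peak. p300: MaD/ZyD peaks are
counted in basal-plus-extension regulatory domains (5 kb upstream / 1 kb
downstream basal, extended to the nearest neighboring basal domain, at most
1 Mb from the TSS, clipped to the scaffold; the cited tool's defaults, its
curated-domain feature omitted). A peak overlapping several domains counts in
each. Strictly embryonic genes (no maternal/pre-MBT expression above
threshold) are grouped by the stage group of their maximum expression, ties
to the earlier group.

## Enhancer clusters

p300 peaks within 12.5 kb (gap ≤ 12,500 bp merges; the boundary case merges)
are stitched into regions whose signal is the sum of member signals. Regions
are ranked by signal, both axes rescaled to [0, 1], and the EC cutoff placed
where the curve's tangent has slope 1 — computed as the touch point of the
slope-1 line supporting the curve from below, which coincides with the
derivative criterion for smooth convex profiles (exactly 0.5 on y = x²) but
is immune to pointwise noise in discrete slopes; with several touch points
the highest-rank one (most stringent cutoff) wins. Exactly linear or
constant profiles have no inflection and flag nothing, with a warning. ECs
are called per stage; their union is the total EC region, against which
per-stage coverage, earliest-stage seeding peaks, label fractions (with
exact cumulative hypergeometric tails for over-/under-representation) and
per-EC MaD/ZyD composition (union bp, no double counting) are measured.

## Motif activity

The response model E_ps = c̃_p + c_s + Σ_m N_pm·A_ms explains the signal of
peak p at stage s (log₂(RPKM+1) by convention; raw mode available) by its
motif counts. Double-centering E removes both offset families in closed
form; the design N is peak-mean-centered correspondingly, after which
A = (N_cᵀN_c + λI)⁻¹ N_cᵀ E_dc. Activities are identifiable only up to a
per-motif constant (absorbed by peak offsets), so they are reported centered
across stages. The ridge parameter defaults to 1.0 and can be chosen by
deterministic K-fold cross-validation over a log grid. Posterior standard
deviations come from the ridge covariance with plug-in residual variance;
z = activity / posterior sd per motif and stage, and a motif is *significant*
when max |z| over stages exceeds the threshold (default 13, the stringent
operating point for clearly driving motifs; the value is configurable since
z-score scales depend on the residual model).

## Methylation

Promoter methylation is coverage-weighted: Σ methylated / Σ covered calls
over CpGs in the window — robust at low coverage, invariant under splitting
a CpG's counts across records, undefined (missing) at zero coverage. CpG
density is observed CG dinucleotides per bp (the observed/expected ratio is
available as an option). Hypomethylation is called either from the Bio-CAP
(non-methylated-CpG capture) over input RPKM ratio on the ±1 kb promoter —
strictly > 1 — or, for bisulfite-style data including the synthetic
methylome, as weighted level < 0.2. Joint tables of gene chromatin label ×
methylation class carry per-cell medians of any covariates; their marginals
equal the classifier's label counts exactly.

## Chromatin-state dynamics

Per-stage segmentations over the seven state groups (Polycomb, poised,
p300-enhancer, transcribed, promoter, heterochromatin, unmodified) are
binned at 200 bp by majority base coverage, ties to the earlier-listed
state, overlapping intervals rejected. The modified genome is every bin with
a non-unmodified state at any stage. Coverage fractions are bp-weighted and
sum to 1 per stage; transition flows between consecutive stages are reported
in bp (bins × 200, terminal scaffold bins at true width — the factor between
bin and bp accounting is exactly the bin size for aligned bins), and the
conservation identities (row sums = source-stage coverage, grand total =
modified-genome size) are asserted on every run, not just in tests.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed); sub-seeds are derived
per generator so partial re-runs are stable.

**Counts.** Replicate ChIP counts are negative binomial with variance
μ(1 + d), where the dispersion d (default 0.1) is the excess Fano factor —
mean-free, so replicate noise stays proportional at enriched and depleted
peaks, and d = 0 degenerates to Poisson. Expected counts are proportional to
peak width (800–1,600 bp, promoter-mark scale) times a log-normal per-peak
strength (ln-sd 0.3, mean-corrected), shared across samples: the across-peak
mean stays at `mean_reads_per_peak` (default 30), M is untouched because the
factor cancels between samples, and the A axis gains the spread that makes
the MA trend identifiable, as in real data. The strength spread is kept
modest deliberately: a merged peak set is left-truncated by the caller's
detection floor, and peaks below ~10 reads are information-theoretically
beyond the count statistic's reach at the published thresholds. True-ZyD
peaks have the α-amanitin mean divided by the depletion factor (default 8)
in both replicates; *ambiguous* peaks in exactly one (random) replicate —
the mechanistic model of the ND class; maternally defined peaks are
undepleted. Background regions carry the matching per-bp rate at
`mean_background_reads` (default 1) per mean peak width — about 3 % of peak
signal, typical for ChIP at called peaks. The first peaks sit centered on
gene TSSs so gene-level classification and the methylome coupling have
substance. Library size is a constant 10⁷: relative RPKM is a within-sample
ratio in which it cancels.

**Not emulated:** read-level data (FASTQ/BAM), fragment-size effects,
GC/mappability bias, peak-boundary uncertainty, and between-replicate
library-size imbalance (the normalization fit would absorb it; tests cover
the mechanism on constructed tables instead). Passing tests therefore
validate the statistical machinery and its thresholds under the stated count
model, not peak calling or alignment.

**Enhancer landscape.** Clusters (default 20) of 6 peaks at 5-kb spacing are
seeded by one peak at the earliest stage and accrue members linearly across
stages; singletons (default 200) and clusters are separated by >25 kb (twice
the stitch distance) so distinct entities never stitch. Cluster member
signal is Exp(1) shifted by +20 over the Exp(1) singleton background —
a cleanly bimodal ranked-signal curve. Cluster members are ZyD with
probability 0.85 and singletons 0.5, echoing the observed ZyD dominance of
ECs.

**Methylome.** Promoter CpG methylation fractions are Beta(1, 19) for
hypomethylated and Beta(12, 3) for hypermethylated promoters; CpG density is
~3× higher in hypomethylated promoters; per-CpG coverage is Poisson(10).
When gene-level chromatin truth is supplied, MaD genes are hypomethylated
with probability 0.85 and ZyD genes methylated with probability 0.95 — the
reported coupling is strong but not perfect, and these defaults mirror that.

**Motifs.** Counts are Poisson(2) over 500 peaks × 20 motifs; 3 active
motifs carry N(0, 0.5²) activities centered across stages; signal adds
N(0, 1) peak offsets, N(0, 0.5²) stage offsets and N(0, 0.1²) noise.

**States.** Per-bin Markov chains over the seven groups with configurable
per-stage-pair transition matrices (rows must sum to 1 within 1e-9; default
a 0.9-sticky matrix, initial distribution 60 % unmodified). Emitted
segmentations are merged same-state runs, bin-aligned, so binning recovers
the planted matrix exactly.

## Problem sizes and determinism

Default problem sizes (2,000 peaks, 300 genes, 20 clusters + 200 singletons
over five stages, 500 × 20 motif matrices, 20,000 state bins; 100,000 bins
in the flow-conservation check) give each analysis enough events for stable
rates while a full pipeline run takes a couple of seconds. All randomness
flows through numpy Generators seeded from the single configured seed; the
pipeline summary is rounded to 10 decimals and serialized with sorted keys,
so one seed and config reproduce `summary.json` byte for byte.

## Known limitations

- External-input mode covers peak/gene classification through the library
  API; the one-command `run-all` path is synthetic-data-driven.
- The elbow cutoff assumes a convex ranked-signal profile; profiles that are
  concave or linear (no inflection) yield no EC calls by design.
- The Audic–Claverie statistic assumes equal sampling depth after
  normalization; strong residual depth imbalance would bias p-values.
- The z > 13 motif threshold is an operating point, not a calibrated error
  rate; its meaning depends on the residual variance model documented above.
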