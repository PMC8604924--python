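# Methods

This note records the models, parameter choices, and numerical decisions
behind `replitime`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic experiments do and
do not demonstrate.

## Replication timing from read depth

The phenotype is relative replication timing inferred from whole-genome
sequencing read depth of proliferating cell lines. With a fraction *s* of
cells in S phase, the expected copy number of a locus with replicated
fraction *f* ∈ [0, 1] among S-phase cells is

    E[cn] = 2·(1−s) + s·(1+f),

so early loci (large *f*) sit near the fully duplicated copy number. The
pipeline never inverts this map on real data; it treats per-sample
Z-normalized, smoothed copy number as the timing signal, which is standard
for S-phase read-depth timing inference.

### Filtering

Window-level (cohort) filters remove windows overlapping assembly gaps or
supplied SV/CNV intervals, windows whose across-sample median deviates from
the genome's "common" copy number (the median of per-window medians) by more
than 0.4 copies, and windows whose 25th/75th across-sample percentile
deviates by more than 0.4 copies. Point-level (per-sample) filters mask data
points more than 0.6 copies from the common value, more than 0.25 copies
from their window's across-sample median, or inside sample-private CNVs.
Masked raw values are retained (`removed_values`) because the rtQTL
artifact filter tests associations on exactly those removed points.
Reference medians for the point filter are computed over all data points of
surviving windows, including previously masked points, making the filters
idempotent. The result is the "filtered raw" state.

### Normalization and smoothing

Each sample is Z-normalized over its unmasked autosomal points (mean 0,
SD 1 with the n−1 divisor) and smoothed with a penalized smoothing spline
(`scipy.interpolate.make_smoothing_spline`) per contiguous segment, with x
in window-index units so the penalty has a stable scale. Gaps shorter than
300 kb are bridged (the spline interpolates per-sample masked points inside
segments); segments shorter than 300 kb are dropped. After smoothing the Z
contract is re-asserted per sample: smoothing removes the window-level noise
share of the variance, and without re-standardization the profile scale
would depend on the raw noise level rather than on biology.

The spline penalty is calibrated, not copied from any specific spline
implementation's parameter: the default (λ = 25 in window-index units) puts
the median per-sample correlation between smoothed and filtered-raw data at
0.95 on the default synthetic cohort, at the representative end of the
0.85–0.95 calibration band. That band does not pin λ uniquely — every λ in
25…25 000 satisfies it at the default cohort's signal-to-noise ratio — so a
second, purpose-specific calibration is used for initiation-site calling:
extrema detection requires the derivative of the residual noise to fall
below the profile slope, which holds at the heavy end of the band
(λ = 6 400, `PEAK_CALL_SMOOTHING_PENALTY`), where the per-sample
local-extrema density matches the expected initiation-site density (~1 per
2 Mb). Association mapping and effect-size estimation use the light end,
which preserves local effect amplitudes.

### PC correction

Sample-space principal components can be removed for visualization-grade
profiles. With `k` given, the top-k components go; the automatic rule
removes components explaining >1% variance whose sample loadings correlate
with no genotype PC (max |r| < 0.2) — technical, not genetic, structure.
The residual is orthogonal to the removed components by construction;
per-sample re-standardization follows.

## Peaks and variant regions

Per-sample local maxima (strictly greater than both neighbors; plateaus
take the leftmost window; NaN breaks the sequence) are clustered across
samples by single-linkage agglomerative clustering cut at 200 kb. For 1-D
positions this is exactly the partition at consecutive gaps larger than the
cutoff, which is how it is implemented; `scipy.cluster.hierarchy` serves as
the independent oracle in the tests. Within a cluster a sample keeps only
its peak nearest the cluster center (center recomputed once after pruning);
boundaries are the full member range (or the 5th–95th percentile in
"trimmed" mode); clusters supported by ≤10% of samples are dropped.
Valleys (terminus proxies) use the same machinery on minima.

Variant regions start from local maxima of the smoothed across-sample SD
track exceeding the genome-wide mean SD, are confirmed when any sample
pair's Welch t-test on filtered-raw values in the 500 kb centered window
passes 0.05 after Bonferroni correction over pairs × candidates, extended
in 200 kb windows sliding 100 kb until fewer than 0.1% of pairs are
nominally significant (the nominal 0.05 level is used for the extension
criterion), merged when overlapping regions' SD-peak profiles correlate
above 0.9 and otherwise split at the intervening SD minimum. A region is
removed when masking the most extreme ⌈1%⌉ of samples at its SD peak
abolishes the SD-peak criterion — the operational form of "driven by ≤1% of
samples".

## cis-rtQTL mapping

Genotype QC requires MAF ≥ 5%, Hardy–Weinberg p ≥ 1e−3 (1-df chi-squared),
biallelic coding and all three genotype classes. Covariates are an
intercept, the top genotype PCs (default 3) and the top phenotype PCs of
the filtered-raw matrix (default 3 on synthetic cohorts; select with
`select_phenotype_pcs`, which maximizes the significant-window count).

Associations are correlations between covariate-residualized phenotype and
dosage, converted to two-sided p-values with df = n − c − 1 (c covariate
columns including the intercept); with no covariates this reduces exactly
to the textbook simple-regression t-test. Permutations shuffle the
residualized phenotype **and re-residualize it on the covariates**:
permutation breaks orthogonality to the covariate space, and skipping the
re-projection deflates the null correlations and makes window-level
p-values anti-conservative (this was the largest single correctness trap in
development).

The window-level p compares the observed minimum cis p-value with a beta
distribution fitted to its permutation null (method-of-moments start,
maximum-likelihood refinement, empirical fallback with a +1 pseudocount).
Permutations are adaptive: batches of 100/150/250/500 stop once 25 null
exceedances accumulate, so unremarkable windows stop after one batch while
windows near the significance boundary continue to the 1 000 cap; the
early-stop threshold only ever triggers for windows with p̂ ≳ 0.25, far
from any decision boundary. The genome-wide scan shares one set of
permutation orders across windows (drawn once from the model seed), which
turns the scan into a handful of BLAS products per chromosome chunk without
changing any window's marginal null distribution; the single-window
`window_scan` entry point seeds its stream from (seed, window id) instead.

Significant windows are selected by Benjamini–Hochberg at 10% FDR (a
deterministic substitute for π₀-estimating q-values at these problem
sizes; 5% is a flag away). Each significant window then receives an
empirical variant threshold p_t: the largest observed p-value at which
(mean number of permutation p-values ≤ p_t over 500 permutations) /
(number of real p-values ≤ p_t) stays at or below the FDR level.

Signals are defined by greedy LD peeling (lowest-p variant tags a signal;
all significant variants with r² ≥ 0.2 join it; ties break toward the
smaller coordinate), kept only with ≥10 members and tag p < 1e−3,
consolidated across windows (tag LD r² ≥ 0.2, window correlation R² ≥ 0.1,
distance < 2 Mb, union-find), and conditionally split: with the tag as an
additional covariate, members passing Bonferroni-corrected p < 0.05 seed a
new signal (provenance recorded). LD comes from cohort dosages by default;
the provider is pluggable. Associated regions extend bidirectionally from
the strongest tag-associated window while p ≤ 0.05.

The CNV-artifact filters evaluate the tag against three data states: the
raw support count (≥5 windows at p < 0.05), the raw-vs-smoothed minimum-p
order-of-magnitude rule (one order, strict log10 inequality), the
removed-data-vs-raw rule (one order, relaxed to two/four orders for top
p ≤ 5e−6 / 5e−8), the count of removed windows beating the raw minimum
(≤2, relaxed to 3 for top p ≤ 5e−8), and the weak-association rule (raw
minimum p < 0.01, region > 1 window). Genomic inflation is the median
observed chi-squared over the analytic χ²₁ median (≈0.4549, computed, not
hard-coded). Cohort merging drops a second-cohort signal when a member
within two orders of magnitude of its top p belongs to a first-cohort
signal with the same effect direction. Validation tests the top variant
(or a member within two orders of magnitude when absent) at the nearest
timing locus in each validation cohort; the cohort-level binomial parameter
for d datasets is 1 − (1 − α/2)^d (0.0963 for d = 4, α = 0.05).

## Multi-rtQTL architecture

Signals group into a multi-rtQTL region when their strongest loci correlate
(R² ≥ 0.2), lie within 2 Mb, and each adds explanatory power — an
unoperationalized phrase implemented as a nested-model F-test (all member
tags vs dropping the candidate, p < 0.05, pruning the weakest failing
member iteratively). LD between tags does not block grouping; only the
F-test prunes. Pooled additivity regresses timing at the primary's focal
locus on the summed early-allele count; `standardize="zscore"` gives the
relative-timing variant, `"none"` keeps profile Z units so the slope
estimates the per-allele effect directly. The additive-vs-synergistic LRT
frees the effective dosages of the 0- and 4-allele groups (equivalently,
their group means around the line through the middle dosages), profiles the
Gaussian variance out (−2·logLR = n·log(RSS₀/RSS₁)) and uses 2 df.
Interaction scans code genotypes −1/0/1 and Bonferroni-correct the
interaction-term p over tested pairs, after pruning windows at r > 0.5 and
variants at LD r² > 0.5. The spatial test shifts each primary/secondary
pair rigidly by 1–2 Mb (random sign, reflected at the matrix edge),
compares the observed median contact with the permutation mean/SD by a
one-sided Z test, and reports a Shapiro–Wilk p for the normality of the
permutation medians.

## Chromatin analyses

Matched control tags must lie ≥2 Mb from the real tag and match it on MAF
(<5% difference), distance to the nearest initiation site and terminus
(<50 kb; peak-cluster centers and valley centers serve as those
catalogues), mean timing (<0.5 Z), and LD-partner count (≥ the tag's).
Signals with <200 matches are excluded from enrichment denominators. Each
permutation replaces every signal with the LD partners of a random matched
tag, subsampled to the signal's member count. Enrichment is a one-tailed
binomial test of the overlapping-signal count with the permutation mean
fraction as parameter (100 permutations by default), BH-adjusted within a
feature category.

The combination search treats each rtQTL SNP independently: level 1 tests
each feature two-sided by Fisher's exact test against pooled control SNPs
(BH at 5% FDR; enrichment or depletion reportable), deeper levels restrict
real and control SNPs to carriers of an enriched combination and test each
additional feature one-sided, until a level adds nothing. When fewer than
five control SNPs carry the parent combination the test falls back to the
feature's marginal control rate via a binomial tail — with independently
placed background marks the conditional and marginal rates coincide, and
without the fallback deep levels would be untestable at realistic control
pool sizes. me3-ac-hyper regions are mutual-overlap intervals of a five-mark
combination that overlap ≥11 distinct variable acetylation marks, merged
within 10 kb; the acetylation panel is configuration, not hard-coded.

Allelic covariation compares the fraction of early-homozygous
(sample, site) pairs carrying a mark with a two-tailed binomial whose
parameter is p_late × (p_perm_early / p_perm_late), the permutation
fractions coming from matched SNPs with a randomly designated early allele
(10 permutations; the ratio is clipped to [0.01, 100] against degenerate
denominators); Bonferroni over the mark panel. The TF test weights each
rtQTL by |Δ motif score| between the early and late allele (lowest-p member
in the TF's table; early allele by the member's beta sign), compares
early-higher vs late-higher totals with permuted-control totals in a 2×2
chi-squared (no continuity correction), excludes TFs overlapping <15
rtQTLs, and BH-adjusts at 10% FDR.

## Prediction

Distances are zero for regions intersecting a peak boundary interval and
otherwise the bp gap from the region edge to the nearest boundary.
Fractional distance — never defined in the timing literature precisely —
is the physical distance divided by half the span between the two flanking
peak centers (0 at a peak, 1 at the midpoint; chromosome ends use the
single flanking span). Shift permutations move each region by 1–2 Mb with
random sign, reflecting at chromosome ends; fold improvement is the null
median over the observed median and the one-sided Wilcoxon rank-sum p
compares distance distributions. PPV = fraction of regions within the
cutoff of a peak; sensitivity = fraction of peaks within the cutoff of a
region; both get shift-permutation Z tests. ROC positives are sampled peak
windows, negatives windows >750 kb from any peak center (both restricted
to analyzable windows, sampled without replacement, shrunk with a warning
when scarce); a window is called "peak" when its center is within the
cutoff of a region; AUC is the trapezoid over the sorted curve.

## The synthetic generator

The generator defines the study conditions; every acceptance experiment
runs on it. Baseline timing zigzags between early peaks (~every 2 Mb,
±15% jitter, heights 1–2 Z) and late valleys (−2…−1 Z) with
piecewise-cosine interpolation, so the derivative vanishes only at true
extrema — replication profiles alternate between initiation peaks and
terminus valleys without flat plateaus, and flat stretches would otherwise
sprout noise-driven local maxima that chain peak clusters together.
Genotypes live in LD blocks (default 50 kb, variants every 5 kb): each
block has a haplotype pair per sample and per-variant mutation flips
(rate 0.03), giving r² that decays with the flip rate; across blocks,
independence. MAFs are drawn and enforced within the configured range.
Planted rtQTLs pick a causal variant near every k-th true peak (all three
genotype classes, MAF nearest the range midpoint) and add
effect × dosage × kernel to timing, with a triangular kernel tapering to
zero over 400 kb (total affected span ~800 kb, matching the scale of
observed rtQTL-associated regions). CNVs add copy-number deltas in random
carriers; histone marks combine uniform background intervals, co-placement
at true peaks (one decision per peak), genotype-conditional per-sample
presence at planted rtQTLs (odds multiplier per early allele; odds 1 is
the null), and jointly placed combination marks at a fraction of rtQTL
member SNPs.

Timing maps to copy number through a logistic with scale 10 Z: the
derivative stays within ~3% of its central value over |t| ≤ 3.5 (the most
extreme peak plus a homozygous effect), so planted Z-unit effects survive
the round trip through copy number, normalization and smoothing essentially
unattenuated, while the replicated fraction stays bounded for arbitrary
inputs. Default depth is 300 000 per 10 kb window — summed per-base
coverage at ~30×. Counts are Poisson around depth·cn/2; at base-pair
resolution a Poisson understates the block correlation of reads, a
simplification the experiments inherit. Residual technical noise defaults
to 0.003 copies. One global seed feeds deterministic substreams
(genotypes, baseline, planting, noise, counts, CNVs, epigenome); identical
configs give byte-identical cohorts.

What the generator does **not** emulate: GC-content bias and mappability
structure, reference-panel LD (cohort LD stands in), population
stratification, X-chromosome dosage, sequence-level reads, cell-line
culture artifacts beyond simple CNVs, and realistic histone-mark spatial
correlation. Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under the stated model — not that real-data
preprocessing (alignment, imputation, GC correction) is handled.

## Experiment problem sizes

The calibration experiments choose sizes that exercise every stage on a
single CPU in minutes: null FDR control uses 20 cohorts of 100 samples ×
2 000 windows × ~5 000 variants; rtQTL recovery plants 20 rtQTLs (0.6 Z
per allele, MAF 0.25–0.35, n = 150) on two 50 Mb chromosomes, so effect
regions cover ~16% of windows and the Z scale itself stays essentially
effect-free; LRT calibration simulates 1 000 additive two-locus regions;
the combination search plants a three-mark trio at 40% of rtQTL member
SNPs over a 2% background with twelve features; prediction uses two 100 Mb
chromosomes (~100 true peaks) with regions planted within 5 kb of an exact
60% subset of peaks and 20 shifted-null ROC replicates; inflation uses 1e5
chi-squared draws.

## Known limitations

- LD is estimated from cohort dosages; small cohorts overestimate r² noise.
- The beta approximation extrapolates window p-values below the permutation
  resolution; extremely significant windows inherit its tail behaviour.
- The conditional-split scan conditions only on accumulated tags (up to
  four rounds); colinear multi-causal configurations beyond that are
  reported as single signals.
- The combination search's marginal-rate fallback assumes background marks
  are placed independently; strongly co-structured control epigenomes would
  need larger control pools instead.
- `spatial_proximity_test` linearizes chromosomes through the supplied
  offsets; trans-chromosomal contact structure is whatever the supplied
  matrix encodes.
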