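# replitime

Genetics of DNA replication timing from population-scale whole-genome
sequencing of proliferating cell lines.

When a substantial fraction of cells in a culture is in S phase, sequencing
read depth fluctuates along chromosomes: early-replicating loci are already
duplicated in more cells and show higher copy number. `replitime` turns
windowed read-depth matrices from such cohorts into replication-timing
profiles and then asks where the genome's replication program is under
genetic control:

- **Profile inference** — per-window copy number is filtered (assembly gaps,
  SVs/CNVs, cohort-level and per-sample outliers), Z-normalized per sample
  (autosomal mean 0, SD 1) and smoothed with a penalized spline per
  contiguous segment, bridging only gaps shorter than 300 kb.
- **Feature calling** — replication initiation-site proxies (peaks of the
  smoothed profile, clustered across samples by single-linkage at 200 kb,
  supported by >10% of samples) and inter-individual variant regions
  (SD-track peaks confirmed by Bonferroni-corrected pairwise t-tests in
  500 kb windows, then extended and merged/split).
- **cis-rtQTL mapping** — for each 10 kb window, variants within 1 Mb are
  tested against timing with genotype- and phenotype-PC covariates. A
  permutation null of the minimum variant p-value (beta-approximated) gives
  a window-level p; windows are selected at 10% FDR (Benjamini–Hochberg); a
  per-window empirical threshold p_t (mean permutation count passing /
  real count passing ≤ FDR) defines significant variants; greedy LD clumping
  (r² ≥ 0.2), consolidation, conditional splitting, associated regions, and
  CNV-artifact filters yield independent rtQTL signals.
- **Multi-rtQTL architecture** — signals sharing a region (correlated loci,
  <2 Mb, each adding explanatory power) are grouped; pooled regression of
  relative timing on the count of early-replicating alleles tests
  additivity; a likelihood-ratio test (χ², 2 df) compares the additive
  dosage model against one with free effective dosages for the 0- and
  4-allele groups; pairwise interactions use −1/0/1 coding; spatial
  proximity uses a 1–2 Mb shift permutation on a Hi-C-style contact matrix.
- **Chromatin** — enrichment of histone marks / TF binding at rtQTL SNPs
  against matched control SNPs (matched on MAF, distance to the nearest
  initiation site and terminus, timing, and LD-partner count), an iterative
  Fisher's-exact search for enriched mark combinations, construction of
  "me3-ac-hyper" regions (trimethylation combinations overlapping ≥11
  acetylation marks, merged within 10 kb), allelic covariation of marks with
  rtQTL genotype, and a motif-score test for TFs whose binding is altered by
  early- vs late-replicating alleles.
- **Prediction** — how well an interval set predicts initiation sites:
  distances to peak boundaries, 1–2 Mb shift-permutation baselines, PPV and
  sensitivity at 10 kb, and ROC/AUC from sampled peak windows vs windows
  >750 kb from any peak.

A synthetic-cohort generator (`replitime.synthetic`) produces all of the
above inputs with a planted truth table — baseline timing with known peaks,
LD-structured genotypes, additive rtQTL effects, CNVs, and histone tracks
optionally coupled to genotype — so the full pipeline is testable offline.

## Worked example

```python
from replitime import CohortConfig, RtQTLModel, simulate_cohort
from replitime.profiles import (filter_windows_global,
                                filter_points_per_sample, normalize_and_smooth)

cohort = simulate_cohort(CohortConfig(n_samples=100, chrom_length=20_000_000,
                                      n_rtqtls=5, effect_size=0.6,
                                      maf_range=(0.25, 0.35), seed=11))
filtered_raw = filter_points_per_sample(filter_windows_global(cohort.depth))
smoothed = normalize_and_smooth(filtered_raw)

model = RtQTLModel(smoothed, cohort.genotypes, raw=filtered_raw, n_phenotype_pcs=2)
res = model.fit(seed=11)
print(res.summary())
```

prints (abridged):

```
cis-rtQTL mapping results
============================================================
samples:              100
windows tested:       2000
significant windows:  306 (BH FDR 0.10)
variants after QC:    3998
independent signals:  8
passing all filters:  6
------------------------------------------------------------
         tag  chrom        pos      top_p  members  region_kb
      rs3398   chr1   16992500   6.14e-41       10        710
       rs995   chr1    4977500   2.87e-34       10        680
      rs1751   chr1    8757500   2.93e-33       10        670
       rs235   chr1    1177500   2.93e-25       10        620
      rs2674   chr1   13372500   3.00e-23       10        730
      ...
```

The five planted rtQTLs (rs235, rs995, rs1751, rs2674, rs3398) are
recovered as the five strongest tags (p ≤ 3e-23, associated regions of
620–730 kb spanning the planted ~800 kb effect footprints); the weaker
entries are borderline signals that the CNV-artifact filters then mostly
remove (6 of 8 signals pass all filters). `res.signals_frame()` returns the
same table as a DataFrame, and `res.plot_signal(res.signals[0])` draws the
cohort's timing profiles around a signal colored by tag genotype.

The same pipeline is scriptable from the shell:

```bash
replitime --config config.yaml --outdir out --seed 1 all
```

with verbs `simulate`, `profile`, `features`, `map`, `multi`, `chromatin`,
`predict`, `all`; every stage writes TSV/BED/JSON plus a run manifest and
can be re-run standalone on saved intermediates.

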