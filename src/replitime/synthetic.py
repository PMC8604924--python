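"""Synthetic replication-timing cohorts with a planted truth table.

The generator emulates the data regime the pipeline assumes: a cohort of
proliferating cell lines (a substantial fraction of cells in S phase) whose
whole-genome read depth fluctuates along chromosomes because early-replicating
loci are duplicated in more cells. On top of a shared smooth multi-peak timing
baseline it plants additive cis-acting timing QTLs (rtQTLs), LD-structured
genotypes, copy-number variants, and per-sample histone-mark tracks whose
presence can co-vary with rtQTL genotype. The returned :class:`SyntheticTruth`
is the oracle every downstream stage is tested against.

Model
-----
True timing (Z units) per sample s, window w:

    t_sw = baseline_w + sum_q  beta_q * dosage_sq * k_q(w)

with a triangular kernel k_q tapering linearly to zero over a half-width
around the affected peak. Timing maps to expected copy number through the
fraction of S-phase cells (``s_phase_fraction``, s):

    E[cn] = 2*(1-s) + s*(1 + f(t)),   f(t) = 1 / (1 + exp(-t))

so early loci (high t) approach the fully-duplicated copy number and late
loci the unreplicated one. Window read counts are Poisson around
``depth_per_window * cn / 2``; the raw matrix handed to the profile stage is
the copy-number estimate 2*counts/depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .grid import GenomeGrid, Intervals
from .rtmatrix import RTMatrix
from .tracks import IntervalTrackSet


@dataclass
class MarkSpec:
    """One histone mark: background placement rate, peak co-placement, genotype coupling.

    ``coupling_odds`` is the per-early-allele odds multiplier on mark presence at a
    planted rtQTL; 1.0 means presence is independent of genotype (the null).
    """

    background_per_mb: float = 2.0
    at_peak_prob: float = 0.0
    coupling_odds: float = 1.0
    base_prob: float = 0.5
    length: int = 2000

    def __post_init__(self):
        if self.coupling_odds < 0:
            raise ValueError("coupling odds must be >= 0")


@dataclass
class ComarkGroup:
    """Marks co-placed (jointly, shared across samples) at a fraction of rtQTL member SNPs."""

    marks: tuple[str, ...]
    snp_prob: float = 0.4


@dataclass
class CohortConfig:
    n_samples: int = 100
    n_chromosomes: int = 1
    chrom_length: int = 20_000_000
    window_size: int = 10_000
    s_phase_fraction: float = 0.45
    depth_per_window: float = 300_000.0
    noise_sd: float = 0.003
    n_rtqtls: int = 10
    effect_size: float = 0.6
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 50_000
    variant_spacing: int = 5_000
    ld_mutation_rate: float = 0.03
    effect_halfwidth: int = 400_000
    peak_spacing: int = 2_000_000
    cnv_spec: list[tuple[int, float, float]] = field(default_factory=list)
    epigenome_spec: dict[str, MarkSpec] = field(default_factory=dict)
    comark_spec: list[ComarkGroup] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples, self.n_chromosomes, self.chrom_length, self.window_size) <= 0:
            raise ValueError("dimensions must be positive")
        if self.chrom_length % self.window_size:
            raise ValueError("window_size must divide chrom_length")
        if not 0 < self.s_phase_fraction < 1:
            raise ValueError("s_phase_fraction must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must be non-degenerate and within (0, 0.5]")
        if self.ld_block_size < self.variant_spacing:
            raise ValueError("ld_block_size must be >= variant spacing")
        if self.n_rtqtls > 0 and 2 * self.effect_halfwidth >= self.chrom_length:
            raise ValueError("rtQTL effect interval exceeds chromosome length")
        for length, _delta, frac in self.cnv_spec:
            if length <= 0 or length > self.chrom_length or not 0 <= frac <= 1:
                raise ValueError(f"invalid cnv_spec entry length={length} frac={frac}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def grid(self) -> GenomeGrid:
        return GenomeGrid.uniform({c: self.chrom_length for c in self.chrom_names}, self.window_size)


@dataclass
class PlantedRtQTL:
    variant_index: int
    variant_id: str
    chrom: str
    peak_pos: int
    interval: tuple[int, int]
    effect_per_allele: float
    member_snps: np.ndarray  # variant indices in LD (r^2 >= 0.2) with the causal variant


@dataclass
class SyntheticTruth:
    baseline: np.ndarray  # (n_windows,)
    true_timing: np.ndarray  # (n_samples, n_windows)
    planted_rtqtls: list[PlantedRtQTL]
    true_peaks: pd.DataFrame  # columns chrom, pos
    peak_intervals: Intervals
    true_cnvs: dict[int, list[tuple[str, int, int, float]]]  # sample -> (chrom, start, end, delta)
    mark_couplings: dict[str, dict[int, float]]  # mark -> dosage -> presence prob
    comark_sites: dict[tuple[str, ...], np.ndarray]  # group -> variant indices carrying all marks


@dataclass
class SimulatedCohort:
    depth: RTMatrix  # raw copy-number estimates (state "raw")
    counts: np.ndarray  # (n_samples, n_windows) Poisson read counts
    expected_cn: np.ndarray  # noise-free expected copy number
    genotypes: GenotypeTable
    tracks: IntervalTrackSet
    truth: SyntheticTruth


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


#: Scale (in timing Z units) of the logistic timing -> replication-fraction map.
#: Chosen so the map is near-linear over the operating range: the logistic
#: derivative stays within ~3% of its central value for |timing| <= ~3.5 Z
#: (the most extreme peak plus a homozygous rtQTL effect), so planted Z-unit
#: effects survive the copy-number round trip essentially unattenuated while
#: the fraction remains bounded in [0, 1] for arbitrary inputs.
TIMING_TO_FRACTION_SCALE = 10.0


def replication_fraction(timing: np.ndarray, scale: float = TIMING_TO_FRACTION_SCALE) -> np.ndarray:
    """Monotone logistic map from timing Z-score to fraction replicated in S cells."""
    return 1.0 / (1.0 + np.exp(-np.asarray(timing) / scale))


def _baseline_timing(config: CohortConfig, rng: np.random.Generator):
    """Smooth multi-peak baseline (Z scale) plus the true peak catalogue.

    Timing zigzags between early peaks and late valleys with piecewise-cosine
    interpolation: the derivative vanishes only at the true extrema, the way
    replication-timing profiles alternate between initiation-site peaks and
    terminus valleys without flat plateaus.
    """
    grid = config.grid()
    centers = grid.centers
    baseline = np.zeros(grid.n_windows)
    peaks = []
    for chrom in config.chrom_names:
        sl = grid.chrom_slice(chrom)
        # jittered peak positions every ~peak_spacing, valleys midway
        ppos = []
        pos = config.peak_spacing / 2
        while pos < config.chrom_length - config.peak_spacing / 4:
            jitter = rng.uniform(-0.15, 0.15) * config.peak_spacing
            ppos.append(float(np.clip(pos + jitter, config.peak_spacing * 0.2,
                                      config.chrom_length - config.peak_spacing * 0.2)))
            pos += config.peak_spacing
        ppos = sorted(ppos)
        knots = [0.0]
        values = [rng.uniform(-2.0, -1.0)]  # chromosome starts in a valley
        for i, p in enumerate(ppos):
            knots.append(p)
            values.append(rng.uniform(1.0, 2.0))
            nxt = ppos[i + 1] if i + 1 < len(ppos) else config.chrom_length
            knots.append(0.5 * (p + nxt))
            values.append(rng.uniform(-2.0, -1.0))
        knots = np.asarray(knots)
        values = np.asarray(values)
        x = centers[sl]
        seg = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, len(knots) - 2)
        a, b = knots[seg], knots[seg + 1]
        va, vb = values[seg], values[seg + 1]
        frac = (x - a) / np.maximum(b - a, 1.0)
        baseline[sl] = va + (vb - va) * 0.5 * (1.0 - np.cos(np.pi * frac))
        for p in ppos:
            peaks.append((chrom, int(round(p))))
    baseline = (baseline - baseline.mean()) / baseline.std(ddof=1)
    # refine truth peak positions to the local maxima of the realized baseline
    refined = []
    for chrom, p in peaks:
        sl = grid.chrom_slice(chrom)
        idx = sl.start + np.arange(sl.stop - sl.start)
        local = idx[np.abs(centers[idx] - p) <= config.peak_spacing / 2]
        best = local[np.argmax(baseline[local])]
        refined.append((chrom, int(centers[best])))
    true_peaks = pd.DataFrame(sorted(set(refined)), columns=["chrom", "pos"]).sort_values(
        ["chrom", "pos"]
    ).reset_index(drop=True)
    half = 2 * config.window_size
    peak_iv = Intervals.from_records(
        [(c, max(0, p - half), min(config.chrom_length, p + half)) for c, p in true_peaks.itertuples(index=False)]
    )
    return baseline, true_peaks, peak_iv


def simulate_genotypes(config: CohortConfig, rng: np.random.Generator | None = None) -> GenotypeTable:
    """LD-block genotypes: within a block, variants are mutated copies of a block
    haplotype pair; across blocks, independent. Dosages count alternative alleles."""
    if rng is None:
        rng = _streams(config.seed, 8)[0]
    lo, hi = config.maf_range
    recs = []
    dosage_cols = []
    vid = 0
    for chrom in config.chrom_names:
        positions = np.arange(config.variant_spacing // 2, config.chrom_length, config.variant_spacing)
        blocks = positions // config.ld_block_size
        for b in np.unique(blocks):
            bpos = positions[blocks == b]
            p = rng.uniform(lo, hi)
            hap = rng.random((config.n_samples, 2)) < p  # block haplotype pair
            for pos in bpos:
                best, best_gap = None, np.inf
                for _attempt in range(50):
                    flips = rng.random((config.n_samples, 2)) < config.ld_mutation_rate
                    alleles = hap ^ flips
                    dos = alleles.sum(axis=1).astype(float)
                    freq = dos.mean() / 2
                    maf = min(freq, 1 - freq)
                    if lo <= maf <= hi:
                        best = dos
                        break
                    gap = max(lo - maf, maf - hi)
                    if gap < best_gap:
                        best, best_gap = dos, gap
                dosage_cols.append(best)
                recs.append((chrom, int(pos), f"rs{vid}", "A", "G"))
                vid += 1
    variants = pd.DataFrame(recs, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeTable(variants, np.column_stack(dosage_cols))


def _plant_rtqtls(config, grid, genotypes, baseline, true_peaks, rng):
    """Pick causal variants near distinct true peaks; build taper kernels and truth."""
    n_q = config.n_rtqtls
    planted: list[PlantedRtQTL] = []
    shift = np.zeros((config.n_samples, grid.n_windows))
    if n_q == 0:
        return planted, shift
    usable = true_peaks.reset_index(drop=True)
    if n_q > len(usable):
        raise ValueError(f"cannot plant {n_q} rtQTLs with only {len(usable)} true peaks")
    step = len(usable) / n_q
    chosen = [usable.iloc[int(i * step)] for i in range(n_q)]
    centers = grid.centers
    three = genotypes.has_all_genotype_classes()
    target_maf = 0.5 * (config.maf_range[0] + config.maf_range[1])
    for peak in chosen:
        cand = np.flatnonzero(
            (genotypes.chrom == peak.chrom)
            & (np.abs(genotypes.pos - peak.pos) <= config.effect_halfwidth / 4)
            & three
        )
        if len(cand) == 0:
            raise ValueError(f"no candidate causal variant near peak {peak.chrom}:{peak.pos}")
        mafs = genotypes.maf()[cand]
        causal = int(cand[np.argmin(np.abs(mafs - target_maf))])
        sl = grid.chrom_slice(peak.chrom)
        dist = np.abs(centers[sl] - peak.pos)
        kernel = np.clip(1.0 - dist / config.effect_halfwidth, 0.0, None)
        dos = genotypes.dosages[:, causal]
        shift[:, sl] += config.effect_size * dos[:, None] * kernel[None, :]
        near = genotypes.cis_index(str(peak.chrom), peak.pos, radius=1_000_000)
        r2 = genotypes.ld_r2(causal, near)
        members = near[r2 >= 0.2]
        lo = max(0, int(peak.pos - config.effect_halfwidth))
        hi = min(config.chrom_length, int(peak.pos + config.effect_halfwidth))
        planted.append(
            PlantedRtQTL(
                variant_index=causal,
                variant_id=str(genotypes.ids[causal]),
                chrom=str(peak.chrom),
                peak_pos=int(peak.pos),
                interval=(lo, hi),
                effect_per_allele=config.effect_size,
                member_snps=members,
            )
        )
    return planted, shift


def simulate_epigenome(
    truth: SyntheticTruth,
    genotypes: GenotypeTable,
    spec: dict[str, MarkSpec],
    comark_spec: list[ComarkGroup] | None = None,
    config: CohortConfig | None = None,
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> IntervalTrackSet:
    """Per-sample, per-mark interval tracks.

    Background intervals fall uniformly at ``background_per_mb``; marks are
    co-placed at true peaks with ``at_peak_prob`` (one decision per peak,
    shared across samples); at planted rtQTLs, per-sample presence is drawn
    with genotype-conditional probability derived from ``coupling_odds``.
    """
    comark_spec = comark_spec or []
    if rng is None:
        rng = np.random.default_rng(0)
    if config is not None:
        n_samples = config.n_samples
        chrom_lengths = {c: config.chrom_length for c in config.chrom_names}
    if n_samples is None or chrom_lengths is None:
        raise ValueError("need config or (n_samples, chrom_lengths)")
    for group in comark_spec:
        for m in group.marks:
            if m not in spec:
                raise KeyError(f"unknown mark in comark group: {m}")
    tracks = IntervalTrackSet()
    genome_mb = sum(chrom_lengths.values()) / 1e6
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    cum = np.cumsum(lengths)

    # shared placements: at-peak and co-mark sites
    peak_hits: dict[str, np.ndarray] = {}
    for mark, ms in spec.items():
        peak_hits[mark] = rng.random(len(truth.true_peaks)) < ms.at_peak_prob
    truth.comark_sites = {}
    group_site_idx: list[tuple[ComarkGroup, np.ndarray]] = []
    member_snps = (
        np.unique(np.concatenate([q.member_snps for q in truth.planted_rtqtls]))
        if truth.planted_rtqtls
        else np.array([], dtype=int)
    )
    for group in comark_spec:
        sites = member_snps[rng.random(len(member_snps)) < group.snp_prob]
        truth.comark_sites[tuple(group.marks)] = sites
        group_site_idx.append((group, sites))

    # genotype-conditional presence probabilities at planted rtQTLs
    truth.mark_couplings = {}
    for mark, ms in spec.items():
        logit0 = np.log(ms.base_prob / (1 - ms.base_prob))
        probs = {}
        for g in (0, 1, 2):
            odds = np.exp(logit0) * ms.coupling_odds ** (g - 1)
            probs[g] = float(odds / (1 + odds))
        truth.mark_couplings[mark] = probs

    for mark, ms in spec.items():
        n_bg = rng.poisson(ms.background_per_mb * genome_mb, size=n_samples)
        # per-sample coupled presence at each planted rtQTL
        for s in range(n_samples):
            recs = []
            starts = rng.uniform(0, cum[-1], size=n_bg[s])
            ci = np.searchsorted(cum, starts, side="right")
            offs = starts - np.concatenate([[0], cum[:-1]])[ci]
            for c, off in zip(ci, offs):
                st = int(min(off, chrom_lengths[chroms[c]] - ms.length))
                recs.append((chroms[c], st, st + ms.length))
            for k, (chrom, pos) in enumerate(truth.true_peaks.itertuples(index=False)):
                if peak_hits[mark][k]:
                    st = max(0, pos - ms.length // 2)
                    recs.append((chrom, st, st + ms.length))
            for q in truth.planted_rtqtls:
                g = int(genotypes.dosages[s, q.variant_index])
                if rng.random() < truth.mark_couplings[mark][g]:
                    pos = int(genotypes.pos[q.variant_index])
                    st = max(0, pos - ms.length // 2)
                    recs.append((q.chrom, st, st + ms.length))
            for group, sites in group_site_idx:
                if mark in group.marks:
                    for v in sites:
                        pos = int(genotypes.pos[v])
                        st = max(0, pos - ms.length // 2)
                        recs.append((str(genotypes.chrom[v]), st, st + ms.length))
            tracks.add(mark, Intervals.from_records(recs).merged(), sample=f"S{s:04d}")
    return tracks


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full cohort: copy-number matrix, genotypes, tracks, and truth."""
    r_geno, r_base, r_plant, r_noise, r_counts, r_cnv, r_epi, _ = _streams(config.seed, 8)
    grid = config.grid()
    genotypes = simulate_genotypes(config, r_geno)
    baseline, true_peaks, peak_iv = _baseline_timing(config, r_base)
    planted, shift = _plant_rtqtls(config, grid, genotypes, baseline, true_peaks, r_plant)
    true_timing = baseline[None, :] + shift

    s = config.s_phase_fraction
    cn = 2.0 * (1 - s) + s * (1.0 + replication_fraction(true_timing))
    expected_cn = cn.copy()

    true_cnvs: dict[int, list[tuple[str, int, int, float]]] = {}
    for length, delta, frac in config.cnv_spec:
        chrom = config.chrom_names[int(r_cnv.integers(config.n_chromosomes))]
        start = int(r_cnv.integers(0, config.chrom_length - length))
        carriers = np.flatnonzero(r_cnv.random(config.n_samples) < frac)
        sl = grid.chrom_slice(chrom)
        wsel = np.flatnonzero((grid.centers[sl] >= start) & (grid.centers[sl] < start + length)) + sl.start
        for smp in carriers:
            cn[smp, wsel] += delta
            true_cnvs.setdefault(int(smp), []).append((chrom, start, start + length, float(delta)))

    if config.noise_sd > 0:
        cn = cn + r_noise.normal(0, config.noise_sd, size=cn.shape)
    cn = np.clip(cn, 0.05, None)
    counts = r_counts.poisson(config.depth_per_window * cn / 2.0)
    copy_est = 2.0 * counts / config.depth_per_window

    truth = SyntheticTruth(
        baseline=baseline,
        true_timing=true_timing,
        planted_rtqtls=planted,
        true_peaks=true_peaks,
        peak_intervals=peak_iv,
        true_cnvs=true_cnvs,
        mark_couplings={},
        comark_sites={},
    )
    tracks = simulate_epigenome(
        truth, genotypes, config.epigenome_spec, config.comark_spec, config=config, rng=r_epi
    )
    depth = RTMatrix(grid, copy_est, state="raw")
    return SimulatedCohort(
        depth=depth,
        counts=counts,
        expected_cn=expected_cn,
        genotypes=genotypes,
        tracks=tracks,
        truth=truth,
    )
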