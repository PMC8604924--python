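"""Epigenetic feature analyses at rtQTLs.

Enrichment of interval features at rtQTL SNPs is assessed against matched
control SNPs: for every rtQTL, control tag variants are drawn from the rest
of the genome matched on minor allele frequency, distance to the nearest
replication initiation site and terminus, replication timing, and LD-partner
count, and each permutation substitutes every signal by a matched tag plus
its LD partners. The module also implements the iterative histone-mark
combination search, the construction of me3-ac-hyper regions (trimethylation
combinations coinciding with broad hyperacetylation), allelic covariation of
marks with rtQTL genotype, and the TF motif-score association test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeTable
from .grid import Intervals
from .mapping import RtQTLSignal
from .rtmatrix import RTMatrix
from .tracks import IntervalTrackSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# matched controls


@dataclass
class MatchedControlSet:
    """Per-signal matched tag variants and the machinery to draw control SNP sets."""

    genotypes: GenotypeTable
    matched_tags: dict[int, np.ndarray]  # signal index -> candidate variant indices
    excluded: set[int]  # signal indices with too few matches
    criteria: dict[str, float]
    signal_sizes: dict[int, int]
    ld_r2: float = 0.2
    ld_radius: float = 1_000_000
    _partner_cache: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def partners(self, tag: int) -> np.ndarray:
        """Variants in LD (r^2 >= ld_r2) with a tag, tag included."""
        if tag not in self._partner_cache:
            near = self.genotypes.cis_index(
                str(self.genotypes.chrom[tag]), self.genotypes.pos[tag], self.ld_radius
            )
            r2 = np.atleast_1d(self.genotypes.ld_r2(tag, near))
            self._partner_cache[tag] = near[r2 >= self.ld_r2]
        return self._partner_cache[tag]

    def draw(self, signal_idx: int, rng: np.random.Generator) -> np.ndarray:
        """One permutation's control SNP set for a signal: LD partners of a
        random matched tag, subsampled to the signal's member count."""
        tags = self.matched_tags[signal_idx]
        tag = int(tags[rng.integers(len(tags))])
        part = self.partners(tag)
        k = self.signal_sizes[signal_idx]
        if len(part) > k:
            part = rng.choice(part, size=k, replace=False)
        return np.sort(part)

    @property
    def usable(self) -> list[int]:
        return [i for i in self.matched_tags if i not in self.excluded]


def variant_annotations(
    genotypes: GenotypeTable,
    peaks: np.ndarray | list,
    valleys: np.ndarray | list,
    smoothed: RTMatrix,
) -> pd.DataFrame:
    """Per-variant MAF, distance to nearest peak/valley center, mean timing."""
    peak_pos = {c: np.sort([p for cc, p in peaks if cc == c]) for c in set(c for c, _ in peaks)}
    valley_pos = {c: np.sort([p for cc, p in valleys if cc == c]) for c in set(c for c, _ in valleys)}

    def nearest(table, chrom, pos):
        arr = table.get(chrom)
        if arr is None or len(arr) == 0:
            return np.inf
        i = np.searchsorted(arr, pos)
        d = []
        if i > 0:
            d.append(abs(pos - arr[i - 1]))
        if i < len(arr):
            d.append(abs(pos - arr[i]))
        return min(d)

    mean_timing = np.nanmean(smoothed.values, axis=0)
    rows = []
    for v in range(genotypes.n_variants):
        chrom, pos = str(genotypes.chrom[v]), int(genotypes.pos[v])
        w = smoothed.grid.locate(chrom, pos)
        rows.append(
            dict(
                peak_dist=nearest(peak_pos, chrom, pos),
                valley_dist=nearest(valley_pos, chrom, pos),
                timing=mean_timing[w],
            )
        )
    df = pd.DataFrame(rows)
    df["maf"] = genotypes.maf()
    return df


def build_matched_controls(
    signals: list[RtQTLSignal],
    genotypes: GenotypeTable,
    peaks,
    valleys,
    smoothed: RTMatrix,
    min_matches: int = 200,
    maf_delta: float = 0.05,
    dist_delta: float = 50_000,
    timing_delta: float = 0.5,
    min_tag_distance: float = 2_000_000,
    ld_r2: float = 0.2,
) -> MatchedControlSet:
    """Find all qualifying matched tag variants genome-wide for every signal.

    ``peaks``/``valleys`` are (chrom, position) iterables for initiation-site
    and terminus proxies. Signals with fewer than ``min_matches`` matched
    tags are flagged excluded (they stay out of enrichment denominators).
    """
    ann = variant_annotations(genotypes, list(peaks), list(valleys), smoothed)
    partner_counts = genotypes.ld_partner_count(r2_min=ld_r2)
    matched: dict[int, np.ndarray] = {}
    excluded: set[int] = set()
    sizes: dict[int, int] = {}
    for i, s in enumerate(signals):
        tag = s.tag
        far = (genotypes.chrom != genotypes.chrom[tag]) | (
            np.abs(genotypes.pos - genotypes.pos[tag]) >= min_tag_distance
        )
        ok = (
            far
            & (np.abs(ann["maf"].to_numpy() - ann["maf"][tag]) < maf_delta)
            & (np.abs(ann["peak_dist"].to_numpy() - ann["peak_dist"][tag]) < dist_delta)
            & (np.abs(ann["valley_dist"].to_numpy() - ann["valley_dist"][tag]) < dist_delta)
            & (np.abs(ann["timing"].to_numpy() - ann["timing"][tag]) < timing_delta)
            & (partner_counts >= partner_counts[tag])
        )
        cand = np.flatnonzero(ok & ~np.isnan(ann["timing"].to_numpy()))
        matched[i] = cand
        sizes[i] = s.n_members
        if len(cand) < min_matches:
            excluded.add(i)
            log.info("signal %s: %d matched tags (<%d), excluded", s.tag_id, len(cand), min_matches)
    return MatchedControlSet(
        genotypes=genotypes,
        matched_tags=matched,
        excluded=excluded,
        criteria=dict(
            maf_delta=maf_delta, dist_delta=dist_delta, timing_delta=timing_delta,
            min_tag_distance=min_tag_distance, min_matches=min_matches,
        ),
        signal_sizes=sizes,
        ld_r2=ld_r2,
    )


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentResult:
    feature: str
    n_overlapping: int
    n_total: int
    expected_fraction: float
    fold: float
    p: float
    adjusted_p: float = np.nan

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ValueError("p must be in (0, 1]")


def feature_enrichment(
    signals: list[RtQTLSignal],
    feature: Intervals,
    controls: MatchedControlSet,
    genotypes: GenotypeTable,
    n_perm: int = 100,
    seed: int = 0,
    feature_name: str = "feature",
) -> EnrichmentResult:
    """One-tailed binomial enrichment of a feature at rtQTLs vs matched controls.

    A signal counts as overlapping when at least one member SNP falls inside
    the feature; the binomial parameter is the mean overlap fraction of the
    matched control sets over ``n_perm`` permutations.
    """
    if len(feature) == 0:
        raise ValueError("empty feature track")
    rng = np.random.default_rng(seed)
    usable = controls.usable
    if not usable:
        raise ValueError("no signals with enough matched controls")

    def frac_overlapping(sets: dict[int, np.ndarray]) -> float:
        k = 0
        for i in usable:
            v = sets[i]
            hit = feature.overlaps_points(genotypes.chrom[v], genotypes.pos[v])
            k += bool(hit.any())
        return k / len(usable)

    obs_sets = {i: signals[i].members for i in usable}
    obs_frac = frac_overlapping(obs_sets)
    perm_fracs = np.empty(n_perm)
    for p in range(n_perm):
        perm_fracs[p] = frac_overlapping({i: controls.draw(i, rng) for i in usable})
    param = float(np.clip(perm_fracs.mean(), 1e-9, 1 - 1e-9))
    k = int(round(obs_frac * len(usable)))
    n = len(usable)
    alt = "greater" if obs_frac >= param else "less"
    p_val = stats.binomtest(k, n, param, alternative=alt).pvalue
    return EnrichmentResult(
        feature=feature_name,
        n_overlapping=k,
        n_total=n,
        expected_fraction=param,
        fold=obs_frac / param,
        p=float(max(p_val, 1e-300)),
    )


def adjust_enrichments(results: list[EnrichmentResult], method: str = "fdr_bh") -> None:
    """BH-adjust p-values within one feature category, in place."""
    if not results:
        return
    adj = multipletests([r.p for r in results], method=method)[1]
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)


# ---------------------------------------------------------------------------
# iterative combination search


@dataclass
class CombinationResult:
    combination: frozenset
    level: int
    n_real: int
    k_real: int
    n_ctrl: int
    k_ctrl: int
    odds_ratio: float
    p: float
    adjusted_p: float
    parent: frozenset | None


def _overlap_matrix(features: dict[str, Intervals], chrom, pos, extend_bp: int = 0) -> np.ndarray:
    names = list(features)
    out = np.zeros((len(pos), len(names)), dtype=bool)
    for j, name in enumerate(names):
        iv = features[name]
        if extend_bp:
            df = iv.df.copy()
            df["start"] = np.maximum(0, df["start"] - extend_bp)
            df["end"] = df["end"] + extend_bp
            iv = Intervals(df)
        out[:, j] = iv.overlaps_points(chrom, pos)
    return out


def combination_search(
    features: dict[str, Intervals],
    snp_chrom,
    snp_pos,
    control_chrom,
    control_pos,
    fdr: float = 0.05,
    extend_bp: int = 0,
    max_size: int = 5,
) -> dict[int, list[CombinationResult]]:
    """Iterative search for enriched feature combinations at rtQTL SNPs.

    Each rtQTL SNP is one observation; controls are the pooled matched
    control SNPs. Level 1 tests each feature by two-sided Fisher's exact
    test (enrichment or depletion reportable); deeper levels restrict both
    real and control SNPs to carriers of an enriched combination and test
    each additional feature one-sided (enrichment), BH-corrected within each
    level. The search stops when a level adds nothing or ``max_size`` is hit.
    """
    names = list(features)
    O_real = _overlap_matrix(features, snp_chrom, snp_pos, extend_bp)
    O_ctrl = _overlap_matrix(features, control_chrom, control_pos, extend_bp)
    out: dict[int, list[CombinationResult]] = {}
    min_restricted_controls = 5

    def fisher(mask_r, mask_c, j, alternative):
        kr = int((mask_r & O_real[:, j]).sum())
        nr = int(mask_r.sum())
        kc = int((mask_c & O_ctrl[:, j]).sum())
        nc = int(mask_c.sum())
        if nc >= min_restricted_controls:
            table = [[kr, nr - kr], [kc, nc - kc]]
            odds, p = stats.fisher_exact(table, alternative=alternative)
            return kr, nr, kc, nc, odds, p
        # too few control SNPs carry the parent combination: fall back to the
        # feature's marginal rate among all controls (background marks are
        # placed independently of one another)
        rate = float(np.clip(O_ctrl[:, j].mean(), 1e-9, 1 - 1e-9))
        res = stats.binomtest(kr, nr, rate, alternative="greater" if alternative == "greater" else "two-sided")
        odds = (kr / nr) / rate if nr else 1.0
        return kr, nr, kc, nc, odds, res.pvalue

    # level 1
    level = 1
    tests = []
    for j, name in enumerate(names):
        mask_r = np.ones(len(O_real), dtype=bool)
        mask_c = np.ones(len(O_ctrl), dtype=bool)
        kr, nr, kc, nc, odds, p = fisher(mask_r, mask_c, j, "two-sided")
        tests.append((frozenset([name]), None, kr, nr, kc, nc, odds, p))
    out[1] = _bh_keep(tests, fdr, level)
    current = [r for r in out[1] if r.odds_ratio > 1]  # only enrichment seeds deeper levels

    while current and level < max_size:
        level += 1
        tests = []
        seen: set[frozenset] = set()
        for parent in current:
            pc = [names.index(n) for n in parent.combination]
            mask_r = O_real[:, pc].all(axis=1)
            mask_c = O_ctrl[:, pc].all(axis=1)
            if mask_r.sum() == 0 or mask_c.sum() == 0:
                continue
            for j, name in enumerate(names):
                if name in parent.combination:
                    continue
                combo = parent.combination | {name}
                if combo in seen:
                    continue
                seen.add(combo)
                kr, nr, kc, nc, odds, p = fisher(mask_r, mask_c, j, "greater")
                tests.append((combo, parent.combination, kr, nr, kc, nc, odds, p))
        if not tests:
            break
        kept = _bh_keep(tests, fdr, level)
        if not kept:
            break
        out[level] = kept
        current = kept
    return out


def _bh_keep(tests, fdr, level) -> list[CombinationResult]:
    if not tests:
        return []
    pvals = [t[7] for t in tests]
    rej, adj = multipletests(pvals, alpha=fdr, method="fdr_bh")[:2]
    kept = []
    for (combo, parent, kr, nr, kc, nc, odds, p), r, a in zip(tests, rej, adj):
        if r:
            kept.append(
                CombinationResult(
                    combination=combo, level=level, n_real=nr, k_real=kr,
                    n_ctrl=nc, k_ctrl=kc, odds_ratio=float(odds), p=float(p),
                    adjusted_p=float(a), parent=parent,
                )
            )
    return kept


# ---------------------------------------------------------------------------
# me3-ac-hyper regions


@dataclass
class Me3AcHyperRegion:
    chrom: str
    start: int
    end: int
    combination: tuple[str, ...]
    acetylation_count: int

    def __post_init__(self):
        if self.acetylation_count < 0:
            raise ValueError("negative acetylation count")


def five_mark_sites(tracks: dict[str, Intervals], combination: tuple[str, ...]) -> Intervals:
    """Mutual-overlap intervals of the combination's member marks."""
    out = None
    for mark in combination:
        out = tracks[mark] if out is None else out.intersect(tracks[mark])
    return out if out is not None else Intervals()


def build_me3achyper(
    sites: Intervals,
    acetylation_tracks: dict[str, Intervals],
    combination: tuple[str, ...] = (),
    min_ac: int = 11,
    merge_gap: int = 10_000,
) -> list[Me3AcHyperRegion]:
    """Keep combination sites overlapping >= ``min_ac`` distinct variable
    acetylation marks; merge survivors within ``merge_gap`` bp."""
    if len(sites) == 0:
        return []
    chrom = sites.df["chrom"].to_numpy(dtype=object)
    s = sites.df["start"].to_numpy()
    e = sites.df["end"].to_numpy()
    counts = np.zeros(len(sites), dtype=int)
    for iv in acetylation_tracks.values():
        counts += iv.overlaps_intervals(chrom, s, e).astype(int)
    keep = counts >= min_ac
    if not keep.any():
        return []
    kept = Intervals(sites.df[keep]).merged(gap=merge_gap)
    out = []
    for row in kept.df.itertuples(index=False):
        c = np.zeros(1, dtype=int)
        for iv in acetylation_tracks.values():
            c += iv.overlaps_intervals([row.chrom], [row.start], [row.end]).astype(int)
        out.append(
            Me3AcHyperRegion(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                combination=tuple(combination), acetylation_count=int(c[0]),
            )
        )
    return sorted(out, key=lambda r: (r.chrom, r.start))


# ---------------------------------------------------------------------------
# allelic covariation


@dataclass
class CovariationResult:
    mark: str
    p_early_observed: float
    p_late: float
    p_perm_early: float
    p_perm_late: float
    binomial_parameter: float
    p: float
    adjusted_p: float
    log_ratio: float
    n_early_pairs: int
    k_early_present: int


def _presence(tracks: IntervalTrackSet, marks: tuple[str, ...], sample: str, chrom: str, pos: int) -> bool:
    for m in marks:
        if not tracks.has(m, sample):
            return False
        if not tracks.get(m, sample).overlaps_points([chrom], [pos])[0]:
            return False
    return True


def allelic_covariation(
    snp_indices: np.ndarray,
    early_sign: np.ndarray,
    genotypes: GenotypeTable,
    tracks: IntervalTrackSet,
    marks: list[str | tuple[str, ...]],
    controls: MatchedControlSet | None = None,
    control_snps: np.ndarray | None = None,
    n_perm: int = 10,
    seed: int = 0,
    ratio_clip: tuple[float, float] = (0.01, 100.0),
) -> list[CovariationResult]:
    """Do early-replicating genotypes carry a mark more often than late ones?

    For each mark (or mark combination — all members must be present), the
    fraction of early-genotype (sample, site) pairs carrying the mark is
    compared with a two-tailed binomial whose parameter is
    p_late * (p_perm_early / p_perm_late), the permutation fractions coming
    from matched control SNPs with a randomly designated early allele.
    Bonferroni correction over the tested marks. Monomorphic sites skip.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(genotypes.n_samples)]

    def site_classes(v: int, sign: int):
        dos = genotypes.dosages[:, v]
        early_count = dos if sign >= 0 else 2 - dos
        return early_count  # 2 = early homozygote, 0 = late homozygote

    eligible = []
    for v, sign in zip(snp_indices, early_sign):
        ec = site_classes(int(v), int(sign))
        if (ec == 2).any() and (ec == 0).any():
            eligible.append((int(v), int(sign)))
    if not eligible:
        raise ValueError("no polymorphic sites with both homozygote classes")

    if control_snps is None:
        if controls is None:
            raise ValueError("need matched controls or explicit control SNPs")
        pool = np.unique(np.concatenate([controls.matched_tags[i] for i in controls.usable]))
    else:
        pool = np.asarray(control_snps)

    results = []
    mark_list = [m if isinstance(m, tuple) else (m,) for m in marks]
    for mk in mark_list:
        k_early = n_early = k_late = n_late = 0
        for v, sign in eligible:
            ec = site_classes(v, sign)
            chrom, pos = str(genotypes.chrom[v]), int(genotypes.pos[v])
            for si, smp in enumerate(samples):
                if ec[si] == 1:
                    continue
                present = _presence(tracks, mk, smp, chrom, pos)
                if ec[si] == 2:
                    n_early += 1
                    k_early += present
                else:
                    n_late += 1
                    k_late += present
        p_early = k_early / n_early if n_early else 0.0
        p_late = k_late / n_late if n_late else 0.0

        pe_perm, pl_perm = [], []
        for _ in range(n_perm):
            ke = ne = kl = nl = 0
            for _v, _sign in eligible:
                cv = int(pool[rng.integers(len(pool))])
                csign = 1 if rng.random() < 0.5 else -1
                ec = site_classes(cv, csign)
                chrom, pos = str(genotypes.chrom[cv]), int(genotypes.pos[cv])
                for si, smp in enumerate(samples):
                    if ec[si] == 1:
                        continue
                    present = _presence(tracks, mk, smp, chrom, pos)
                    if ec[si] == 2:
                        ne += 1
                        ke += present
                    else:
                        nl += 1
                        kl += present
            pe_perm.append(ke / ne if ne else 0.0)
            pl_perm.append(kl / nl if nl else 0.0)
        p_perm_early = float(np.mean(pe_perm))
        p_perm_late = float(np.mean(pl_perm))
        ratio = np.clip(
            p_perm_early / p_perm_late if p_perm_late > 0 else ratio_clip[1],
            *ratio_clip,
        )
        param = float(np.clip(p_late * ratio, 1e-9, 1 - 1e-9))
        if n_early == 0:
            continue
        pv = stats.binomtest(k_early, n_early, param, alternative="two-sided").pvalue
        with np.errstate(divide="ignore"):
            lr = np.log(p_early / p_late) if p_late > 0 and p_early > 0 else np.nan
        results.append(
            CovariationResult(
                mark="+".join(mk),
                p_early_observed=p_early,
                p_late=p_late,
                p_perm_early=p_perm_early,
                p_perm_late=p_perm_late,
                binomial_parameter=param,
                p=float(pv),
                adjusted_p=float(min(1.0, pv * len(mark_list))),
                log_ratio=float(lr),
                n_early_pairs=n_early,
                k_early_present=k_early,
            )
        )
    return results


# ---------------------------------------------------------------------------
# TF motif-score association


@dataclass
class MotifAssociation:
    tf: str
    early_weight: float
    late_weight: float
    perm_early_weight: float
    perm_late_weight: float
    n_rtqtls: int
    chi2: float
    p: float
    adjusted_p: float
    log2_ratio: float


def tf_motif_association(
    signals: list[RtQTLSignal],
    motif_scores: pd.DataFrame,
    genotypes: GenotypeTable,
    controls: MatchedControlSet,
    n_perm: int = 100,
    min_overlap: int = 15,
    fdr: float = 0.10,
    seed: int = 0,
) -> list[MotifAssociation]:
    """Weighted allele-direction test of TF binding-affinity changes at rtQTLs.

    ``motif_scores`` columns: variant_id, tf, score_ref, score_alt (log2
    binding-probability scores). Per signal and TF, the lowest-p member SNP
    present in the table contributes |delta| weight to the early- or
    late-higher total, where delta = early-allele score - late-allele score.
    Permutation baselines draw matched control SNPs with random early-allele
    assignment; the 2x2 chi-squared test compares observed vs permuted
    totals. TFs overlapping fewer than ``min_overlap`` rtQTLs are excluded;
    BH correction at ``fdr``.
    """
    rng = np.random.default_rng(seed)
    by_tf = {tf: sub.set_index("variant_id") for tf, sub in motif_scores.groupby("tf")}
    id_of = {v: str(genotypes.ids[v]) for s in signals for v in map(int, s.members)}
    results = []
    raw = []
    for tf, table in by_tf.items():
        early_w = late_w = 0.0
        n_overlap = 0
        for s in signals:
            present = [v for v in map(int, s.members) if id_of[v] in table.index]
            if not present:
                continue
            n_overlap += 1
            v = min(present, key=lambda v: s.member_p[v])
            row = table.loc[id_of[v]]
            beta = s.member_beta.get(v, s.member_beta.get(s.tag, 0.0))
            if beta >= 0:  # alt allele is early
                delta = float(row["score_alt"] - row["score_ref"])
            else:
                delta = float(row["score_ref"] - row["score_alt"])
            if delta > 0:
                early_w += abs(delta)
            elif delta < 0:
                late_w += abs(delta)
        if n_overlap < min_overlap:
            log.info("TF %s overlaps %d rtQTLs (<%d), excluded", tf, n_overlap, min_overlap)
            continue
        pe = pl = 0.0
        id_to_idx = {str(x): j for j, x in enumerate(genotypes.ids)}
        table_idx = [id_to_idx[i] for i in table.index if i in id_to_idx]
        for _ in range(n_perm):
            for i in controls.usable:
                ctrl = controls.draw(i, rng)
                in_table = [v for v in ctrl if id_of.get(v, str(genotypes.ids[v])) in table.index]
                if not in_table:
                    continue
                v = int(in_table[rng.integers(len(in_table))])
                row = table.loc[str(genotypes.ids[v])]
                delta = float(row["score_alt"] - row["score_ref"])
                if rng.random() < 0.5:
                    delta = -delta
                if delta > 0:
                    pe += abs(delta)
                elif delta < 0:
                    pl += abs(delta)
        pe, pl = pe / n_perm, pl / n_perm
        if early_w + late_w == 0 or pe + pl == 0:
            chi2, p = 0.0, 1.0
        else:
            table22 = np.array([[early_w, late_w], [pe, pl]])
            chi2, p = stats.chi2_contingency(table22, correction=False)[:2]
        with np.errstate(divide="ignore"):
            l2r = np.log2(early_w / late_w) if late_w > 0 and early_w > 0 else (np.inf if early_w > 0 else -np.inf)
        raw.append((tf, early_w, late_w, pe, pl, n_overlap, float(chi2), float(max(p, 1e-300)), float(l2r)))
    if not raw:
        return []
    adj = multipletests([r[7] for r in raw], alpha=fdr, method="fdr_bh")[1]
    for (tf, ew, lw, pe, pl, n_o, chi2, p, l2r), a in zip(raw, adj):
        results.append(
            MotifAssociation(
                tf=tf, early_weight=ew, late_weight=lw, perm_early_weight=pe,
                perm_late_weight=pl, n_rtqtls=n_o, chi2=chi2, p=p,
                adjusted_p=float(a), log2_ratio=l2r,
            )
        )
    return results
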