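"""Multi-rtQTL regions: grouping, additivity, interaction and spatial proximity.

A region whose timing is independently associated with two or more signals
is a multi-rtQTL region. Signals group when their most strongly associated
timing loci are correlated (R^2 >= 0.2), lie within 2 Mb, and each member
adds explanatory power in a nested-model F-test. The additive-vs-synergistic
question is posed as a likelihood-ratio test: the null codes genotype as the
0..4 count of early-replicating alleles; the alternative frees the dosage
values of the 0- and 4-allele groups, and -2*log(LR) is referred to a
chi-squared distribution with two degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import GenotypeTable
from .mapping import RtQTLSignal, _UnionFind
from .rtmatrix import RTMatrix

log = logging.getLogger(__name__)


@dataclass
class MultiRegion:
    signals: list[RtQTLSignal]  # ordered by strength, primary first
    pairwise_r2: dict[tuple[int, int], float] = field(default_factory=dict)
    pairwise_dist: dict[tuple[int, int], float] = field(default_factory=dict)
    added_power_p: dict[int, float] = field(default_factory=dict)  # signal idx -> F-test p

    def __post_init__(self):
        if len(self.signals) < 2:
            raise ValueError("a multi-rtQTL region needs at least two signals")

    @property
    def primary(self) -> RtQTLSignal:
        return self.signals[0]

    @property
    def secondaries(self) -> list[RtQTLSignal]:
        return self.signals[1:]


def early_allele_dosage(signal: RtQTLSignal, genotypes: GenotypeTable) -> np.ndarray:
    """Count of early-replicating alleles (0/1/2) at the signal's tag.

    Positive tag beta means the alternative allele advances timing, so the
    alt dosage already counts early alleles; otherwise it is reversed.
    """
    dos = genotypes.dosages[:, signal.tag]
    beta = signal.member_beta.get(signal.tag, 1.0)
    return dos if beta >= 0 else 2 - dos


def _focal_phenotype(signal: RtQTLSignal, matrix: RTMatrix) -> np.ndarray:
    return matrix.values[:, signal.window]


def added_power_pvalue(
    candidate: int, signals: list[RtQTLSignal], y: np.ndarray, genotypes: GenotypeTable
) -> float:
    """Nested-model F-test: all member tags vs the model dropping `candidate`."""
    ok = ~np.isnan(y)
    yv = y[ok]
    full_cols = [genotypes.dosages[ok, s.tag] for s in signals]
    red_cols = [genotypes.dosages[ok, s.tag] for i, s in enumerate(signals) if i != candidate]
    X_full = np.column_stack([np.ones(ok.sum())] + full_cols)
    X_red = np.column_stack([np.ones(ok.sum())] + red_cols)
    rss_full = _rss(X_full, yv)
    rss_red = _rss(X_red, yv)
    df_num = X_full.shape[1] - X_red.shape[1]
    df_den = len(yv) - X_full.shape[1]
    if df_den <= 0 or rss_full <= 0:
        return 1.0
    F = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return float(stats.f.sf(F, df_num, df_den))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def find_multi_regions(
    signals: list[RtQTLSignal],
    smoothed: RTMatrix,
    genotypes: GenotypeTable,
    r2_min: float = 0.2,
    dist_max: float = 2_000_000,
    power_alpha: float = 0.05,
) -> list[MultiRegion]:
    """Group signals into multi-rtQTL regions.

    Edges require correlated strongest loci (R^2 >= r2_min) and distance
    < dist_max; connected components with >= 2 members survive; members not
    adding explanatory power (nested F-test at ``power_alpha``) are pruned.
    LD between tags does not block grouping — only the F-test prunes.
    """
    if len(signals) < 2:
        return []
    grid = smoothed.grid
    uf = _UnionFind(len(signals))
    r2_rec: dict[tuple[int, int], float] = {}
    dist_rec: dict[tuple[int, int], float] = {}
    for i in range(len(signals)):
        for j in range(i + 1, len(signals)):
            a, b = signals[i], signals[j]
            if a.chrom != b.chrom:
                continue
            d = abs(grid.centers[a.window] - grid.centers[b.window])
            if d >= dist_max:
                continue
            x, y = smoothed.values[:, a.window], smoothed.values[:, b.window]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                continue
            r2 = np.corrcoef(x[ok], y[ok])[0, 1] ** 2
            if r2 < r2_min:
                continue
            uf.union(i, j)
            r2_rec[(i, j)] = float(r2)
            dist_rec[(i, j)] = float(d)
    groups: dict[int, list[int]] = {}
    for i in range(len(signals)):
        groups.setdefault(uf.find(i), []).append(i)
    regions: list[MultiRegion] = []
    for member_idx in groups.values():
        if len(member_idx) < 2:
            continue
        members = sorted((signals[i] for i in member_idx), key=lambda s: s.top_p)
        y = _focal_phenotype(members[0], smoothed)
        power: dict[int, float] = {}
        while len(members) >= 2:
            pvals = [added_power_pvalue(c, members, y, genotypes) for c in range(len(members))]
            worst = int(np.argmax(pvals))
            if pvals[worst] < power_alpha:
                power = {c: p for c, p in enumerate(pvals)}
                break
            dropped = members.pop(worst)
            log.info("pruned signal %s from multi region (F-test p=%.3f)", dropped.tag_id, pvals[worst])
        if len(members) < 2:
            continue
        regions.append(
            MultiRegion(
                signals=members,
                pairwise_r2=r2_rec,
                pairwise_dist=dist_rec,
                added_power_p=power,
            )
        )
    return regions


def pooled_additivity(
    regions: list[MultiRegion] | list[RtQTLSignal],
    smoothed: RTMatrix,
    genotypes: GenotypeTable,
    standardize: str = "zscore",
) -> tuple[float, float]:
    """Pooled regression of relative timing on the early-allele count.

    Per region, timing at the primary's focal locus is pooled with the
    summed early-allele dosage over member tags; a positive slope means more
    early alleles -> earlier replication. With ``standardize="zscore"``
    (relative replication timing) the locus is Z-scored across samples
    before pooling; ``"none"`` pools the per-sample-Z profile values
    directly, so the slope is an estimate of the per-allele timing effect in
    profile Z units. Accepts multi-rtQTL regions or bare signals (treated as
    single-member regions). Returns (slope per allele, two-sided p).
    """
    ys, xs = [], []
    for reg in regions:
        if isinstance(reg, RtQTLSignal):
            primary, members = reg, [reg]
        else:
            primary, members = reg.primary, reg.signals
        y = _focal_phenotype(primary, smoothed)
        ok = ~np.isnan(y)
        if standardize == "zscore":
            z = (y[ok] - y[ok].mean()) / y[ok].std()
        else:
            z = y[ok] - y[ok].mean()
        count = np.sum([early_allele_dosage(s, genotypes)[ok] for s in members], axis=0)
        ys.append(z)
        xs.append(count)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(np.unique(x)) < 2:
        raise ValueError("pooled additivity needs at least two distinct allele counts")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def additive_vs_synergistic_lrt(
    y: np.ndarray, dosage: np.ndarray
) -> tuple[float, float]:
    """LRT of the additive (dosage 0..4 linear) vs synergistic model.

    The alternative frees the effective dosage of the 0- and 4-allele groups
    (equivalently, frees those group means around the line fitted to the
    middle dosages). Gaussian likelihood with the variance profiled out:
    -2*log(LR) = n * log(RSS_null / RSS_alt), referred to chi2 with 2 df.
    Requires at least one individual at dosage 0 and one at dosage 4.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage)
    ok = ~np.isnan(y)
    y, dosage = y[ok], dosage[ok]
    if not ((dosage == 0).any() and (dosage == 4).any()):
        raise ValueError("region needs individuals at 0 and 4 early alleles")
    n = len(y)
    X0 = np.column_stack([np.ones(n), dosage.astype(float)])
    mid = ((dosage >= 1) & (dosage <= 3)).astype(float)
    X1 = np.column_stack([
        np.ones(n),
        dosage.astype(float) * mid,
        (dosage == 0).astype(float),
        (dosage == 4).astype(float),
    ])
    rss0 = _rss(X0, y)
    rss1 = _rss(X1, y)
    stat = max(n * np.log(rss0 / rss1), 0.0)  # alternative nests the null
    return float(stat), float(stats.chi2.sf(stat, df=2))


def interaction_scan(
    phenotypes: np.ndarray,
    genotypes: GenotypeTable,
    pairs: list[tuple[int, int, int]],
) -> list[dict]:
    """Pairwise variant interaction test on timing windows.

    ``pairs`` is a list of (window phenotype row index into ``phenotypes``,
    variant i, variant j). Genotypes are coded -1/0/1; the model is
    timing ~ g1 + g2 + g1*g2 and the interaction-term p-value is extracted,
    with Bonferroni correction over the tested pairs.
    """
    results = []
    n_tests = len(pairs)
    for w, vi, vj in pairs:
        y = np.asarray(phenotypes[w], dtype=float)
        g1 = genotypes.dosages[:, vi] - 1.0
        g2 = genotypes.dosages[:, vj] - 1.0
        ok = ~np.isnan(y)
        X = np.column_stack([np.ones(ok.sum()), g1[ok], g2[ok], (g1 * g2)[ok]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            log.info("pair (%d, %d): collinear design, skipped", vi, vj)
            continue
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ beta
        df = ok.sum() - X.shape[1]
        sigma2 = resid @ resid / df
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * XtX_inv[3, 3])
        t = beta[3] / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df)
        results.append(
            dict(window=w, var_i=vi, var_j=vj, interaction_beta=float(beta[3]),
                 p=float(p), p_bonferroni=float(min(1.0, p * n_tests)))
        )
    return results


def prune_for_interaction(
    smoothed: RTMatrix, genotypes: GenotypeTable,
    window_corr_max: float = 0.5, ld_r2_max: float = 0.5,
    windows: np.ndarray | None = None, variants: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy pruning before the genome-wide interaction scan: collapse
    windows correlated above ``window_corr_max`` and variants in LD above
    ``ld_r2_max``."""
    if windows is None:
        windows = np.flatnonzero(~np.isnan(smoothed.values).any(axis=0))
    kept_w: list[int] = []
    for w in windows:
        ok = True
        for k in kept_w:
            if str(smoothed.grid.chrom[w]) != str(smoothed.grid.chrom[k]):
                continue
            a, b = smoothed.values[:, w], smoothed.values[:, k]
            m = ~(np.isnan(a) | np.isnan(b))
            if m.sum() > 2 and abs(np.corrcoef(a[m], b[m])[0, 1]) > window_corr_max:
                ok = False
                break
        if ok:
            kept_w.append(int(w))
    if variants is None:
        variants = np.arange(genotypes.n_variants)
    kept_v: list[int] = []
    for v in variants:
        ok = True
        for k in kept_v:
            if str(genotypes.chrom[v]) != str(genotypes.chrom[k]):
                continue
            if abs(genotypes.pos[v] - genotypes.pos[k]) > 1_000_000:
                continue
            if genotypes.ld_r2(int(v), np.array([k]))[0] > ld_r2_max:
                ok = False
                break
        if ok:
            kept_v.append(int(v))
    return np.asarray(kept_w), np.asarray(kept_v)


def spatial_proximity_test(
    pairs: list[tuple[str, int, str, int]],
    contact_matrix: np.ndarray,
    bin_size: int,
    chrom_offsets: dict[str, int],
    n_perm: int = 100,
    shift_range: tuple[int, int] = (1_000_000, 2_000_000),
    seed: int = 0,
) -> dict:
    """Do primary/secondary pairs sit closer in nuclear space than chance?

    The observed median contact score of the pairs is compared with
    permutations in which each pair keeps its genomic distance but is
    shifted by 1-2 Mb (random sign, reflected at matrix edges). One-sided Z
    test; a Shapiro-Wilk p on the permutation medians reports the normality
    check.
    """
    rng = np.random.default_rng(seed)
    nbins = contact_matrix.shape[0]
    genome_bp = nbins * bin_size

    def score(linear_pairs):
        vals = []
        for a, b in linear_pairs:
            i, j = int(a // bin_size), int(b // bin_size)
            if not (0 <= i < nbins and 0 <= j < nbins):
                raise ValueError(f"pair at linear bp ({a}, {b}) outside the contact matrix")
            vals.append(contact_matrix[i, j])
        return float(np.median(vals))

    linear = [(chrom_offsets[c1] + p1, chrom_offsets[c2] + p2) for c1, p1, c2, p2 in pairs]
    observed = score(linear)
    perm_medians = np.empty(n_perm)
    shifts_used = []
    for k in range(n_perm):
        shifted = []
        for a0, b0 in linear:
            mag = rng.uniform(shift_range[0], shift_range[1])
            shift = rng.choice([-1, 1]) * mag
            a, b = a0 + shift, b0 + shift
            if a < 0 or b < 0 or a >= genome_bp or b >= genome_bp:
                shift = -shift
                a, b = a0 + shift, b0 + shift
            shifts_used.append(abs(shift))
            shifted.append((a, b))
        perm_medians[k] = score(shifted)
    mean, sd = perm_medians.mean(), perm_medians.std(ddof=1)
    z = 0.0 if sd == 0 else (observed - mean) / sd
    p = float(stats.norm.sf(z))
    shapiro_p = float(stats.shapiro(perm_medians).pvalue) if sd > 0 else 1.0
    return dict(
        observed_median=observed, perm_mean=float(mean), perm_sd=float(sd),
        z=float(z), p=p, shapiro_p=shapiro_p,
        shifts=np.asarray(shifts_used), perm_medians=perm_medians,
    )
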