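"""cis-rtQTL mapping.

The model associates the replication timing of each 10 kb window with the
dosages of variants within 1 Mb of the window center (the cis set), after
removing genotype- and phenotype-PC covariates. Mapping is two-step:

1. A window-level p-value per window: the minimum variant p-value is compared
   with its permutation null (phenotype permuted within the covariate
   residual space), summarized by a fitted beta distribution; windows are
   flagged at 10% FDR (Benjamini-Hochberg).
2. A per-window empirical significance threshold p_t: the largest observed
   p-value for which (mean permutation count passing) / (real count passing)
   stays at or below the FDR level.

Significant variants are peeled into independent signals by greedy LD
clumping (r^2 >= 0.2 with the current lowest-p tag), consolidated across
windows, conditionally split, given an associated region, and screened by
CNV-artifact filters that exploit the raw and removed data states.

Usage::

    model = RtQTLModel(smoothed, genotypes, raw=filtered_raw)
    res = model.fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeTable
from .rtmatrix import RTMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# covariates


@dataclass
class CovariateSet:
    """Intercept + genotype PCs + phenotype PCs used in every association test."""

    genotype_pcs: np.ndarray  # (n_samples, g)
    phenotype_pcs: np.ndarray  # (n_samples, k)

    def matrix(self, n_samples: int | None = None) -> np.ndarray:
        parts = [np.ones((self.genotype_pcs.shape[0], 1))]
        if self.genotype_pcs.size:
            parts.append(self.genotype_pcs)
        if self.phenotype_pcs.size:
            parts.append(self.phenotype_pcs)
        X = np.column_stack(parts)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate columns are linearly dependent")
        return X

    @property
    def n_columns(self) -> int:
        return 1 + self.genotype_pcs.shape[1] + self.phenotype_pcs.shape[1]


def genotype_pcs(genotypes: GenotypeTable, k: int = 3) -> np.ndarray:
    z = genotypes.standardized()
    U, S, _ = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    return U[:, :k] * S[:k]


def phenotype_pcs(matrix: RTMatrix, k: int) -> np.ndarray:
    """Sample-space PCs of the (filtered raw) timing matrix; NaNs imputed to window mean."""
    X = matrix.values.copy()
    col_mean = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    X[nan] = np.broadcast_to(col_mean, X.shape)[nan]
    keep = ~np.isnan(X).any(axis=0)
    X = X[:, keep]
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k] * S[:k]


def _orthonormal(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q


def residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Remove the column space of orthonormal Q from each column of M."""
    return M - Q @ (Q.T @ M)


def _unit_rows(M: np.ndarray) -> np.ndarray:
    norm = np.sqrt((M**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    return M / norm


def corr_pvalues(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r**2))
    return 2 * stats.t.sf(np.abs(t), df)


# ---------------------------------------------------------------------------
# result records


@dataclass
class AssociationResult:
    variant: int
    variant_id: str
    window: int
    beta: float
    t_stat: float
    p: float

    def __post_init__(self):
        if not (0 < self.p <= 1) or not np.isfinite(self.beta):
            raise ValueError("invalid association result")


@dataclass
class WindowResult:
    window: int
    min_p_nominal: float
    window_p: float
    n_cis_variants: int
    best_variant: int
    n_perm_used: int = 0
    significant: bool = False


@dataclass
class RtQTLSignal:
    tag: int
    tag_id: str
    members: np.ndarray  # variant indices
    member_p: dict[int, float]
    member_beta: dict[int, float]
    top_p: float
    threshold_pt: float
    chrom: str
    window: int  # window of origin (strongest)
    windows: set[int] = field(default_factory=set)
    associated_region: tuple[int, int] | None = None
    region_windows: tuple[int, int] | None = None  # inclusive window index range
    filter_verdicts: dict[str, bool] = field(default_factory=dict)
    provenance: str = "ld_greedy"
    source: str = ""

    @property
    def passes_filters(self) -> bool:
        return all(self.filter_verdicts.values()) if self.filter_verdicts else True

    @property
    def n_members(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# permutation machinery


@dataclass
class PermutationPolicy:
    """Adaptive schedule: run batches until enough null exceedances are seen.

    Windows whose observed minimum p is clearly unremarkable accumulate null
    exceedances quickly and stop after the first batch; windows near the
    significance boundary continue to the cap, keeping their window_p
    unbiased where it matters.
    """

    batches: tuple[int, ...] = (100, 150, 250, 500)
    min_exceedances: int = 25

    @property
    def cap(self) -> int:
        return sum(self.batches)


def fit_beta_null(null_p: np.ndarray, obs_p: float) -> float:
    """Window-level p from a beta approximation of the null min-p distribution.

    Method-of-moments start refined by maximum likelihood; degenerate fits
    fall back to the empirical permutation p with a +1 pseudocount.
    """
    null_p = np.clip(null_p, 1e-300, 1 - 1e-12)
    empirical = (1 + (null_p <= obs_p).sum()) / (1 + len(null_p))
    m, v = null_p.mean(), null_p.var()
    if v <= 0 or not 0 < m < 1:
        return float(empirical)
    common = m * (1 - m) / v - 1
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    try:
        a, b, _, _ = stats.beta.fit(null_p, a0, b0, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError
        return float(np.clip(stats.beta.cdf(obs_p, a, b), 1e-300, 1.0))
    except Exception:
        return float(empirical)


def window_scan(
    phenotype: np.ndarray,
    window: int,
    chrom: str,
    center: float,
    genotypes: GenotypeTable,
    covariates: CovariateSet | None,
    cis_radius: float = 1_000_000,
    n_perm: int | PermutationPolicy = 1000,
    seed: int = 0,
) -> tuple[WindowResult | None, list[AssociationResult]]:
    """Scan a single window: per-variant associations plus a permutation window p.

    The permutation stream is derived from (seed, window id) so thresholds
    are reproducible window by window.
    """
    cis = genotypes.cis_index(chrom, center, cis_radius)
    if len(cis) == 0:
        log.info("window %d: no cis variants, skipped", window)
        return None, []
    n = len(phenotype)
    if covariates is not None:
        Q = _orthonormal(covariates.matrix())
        c = Q.shape[1]
    else:
        Q = np.ones((n, 1)) / np.sqrt(n)
        c = 1
    df = n - c - 1
    y = residualize(phenotype[:, None], Q)[:, 0]
    G = residualize(genotypes.dosages[:, cis], Q)
    y_sd = y.std()
    g_sd = G.std(axis=0)
    yu = y / np.sqrt((y**2).sum())
    Gu = G / np.sqrt((G**2).sum(axis=0, keepdims=True))
    r = yu @ Gu
    p = corr_pvalues(r, df)
    beta = r * y_sd / np.where(g_sd == 0, 1.0, g_sd)
    t = r * np.sqrt(df / np.clip(1 - r**2, 1e-15, None))
    assoc = [
        AssociationResult(int(v), str(genotypes.ids[v]), window, float(b), float(ts), float(pv))
        for v, b, ts, pv in zip(cis, beta, t, p)
    ]
    best = int(np.argmin(p))
    obs_min_p = float(p[best])

    policy = n_perm if isinstance(n_perm, PermutationPolicy) else PermutationPolicy(batches=(int(n_perm),))
    rng = np.random.default_rng(np.random.SeedSequence((seed, window)))
    obs_max_r = np.abs(r).max()
    null_max_r = []
    exceed = 0
    done = 0
    for b in policy.batches:
        orders = np.argsort(rng.random((b, n)), axis=1)
        Yp = yu[orders]  # (b, n)
        # re-residualize on the covariates: permutation breaks orthogonality
        Yp = Yp - (Yp @ Q) @ Q.T
        norm = np.sqrt((Yp**2).sum(axis=1, keepdims=True))
        norm[norm == 0] = 1.0
        Yp = Yp / norm
        R = np.abs(Yp @ Gu).max(axis=1)
        null_max_r.append(R)
        exceed += int((R >= obs_max_r).sum())
        done += b
        if exceed >= policy.min_exceedances:
            break
    null_max_r = np.concatenate(null_max_r)
    null_min_p = corr_pvalues(null_max_r, df)
    window_p = fit_beta_null(null_min_p, obs_min_p)
    wr = WindowResult(
        window=window,
        min_p_nominal=obs_min_p,
        window_p=window_p,
        n_cis_variants=len(cis),
        best_variant=int(cis[best]),
        n_perm_used=done,
    )
    return wr, assoc


def significant_windows(window_results: list[WindowResult], fdr: float = 0.10) -> set[int]:
    """Benjamini-Hochberg over window-level p-values; flags the results in place."""
    if not window_results:
        return set()
    p = np.array([w.window_p for w in window_results])
    rej, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")[:4]
    out = set()
    for w, r in zip(window_results, rej):
        w.significant = bool(r)
        if r:
            out.add(w.window)
    return out


def variant_threshold(
    real_p: np.ndarray, perm_p: np.ndarray, n_perm: int | None = None, fdr: float = 0.10
) -> float | None:
    """Per-window empirical FDR threshold p_t.

    FDR(p_t) = (mean number of permutation p-values <= p_t) / (number of real
    p-values <= p_t); p_t is the largest observed p-value keeping this <= fdr.
    ``perm_p`` may be an (n_perm, m) matrix or a flat array with ``n_perm`` given.
    """
    real_p = np.sort(np.asarray(real_p, dtype=float))
    perm = np.asarray(perm_p, dtype=float)
    if perm.ndim == 2:
        n_perm = perm.shape[0]
        perm = perm.ravel()
    elif n_perm is None:
        raise ValueError("flat perm_p needs n_perm")
    perm = np.sort(perm)
    real_count = np.arange(1, len(real_p) + 1)
    fp_mean = np.searchsorted(perm, real_p, side="right") / n_perm
    ok = fp_mean / real_count <= fdr
    if not ok.any():
        return None
    return float(real_p[ok].max())


# ---------------------------------------------------------------------------
# signals


def define_signals(
    assoc: list[AssociationResult],
    threshold_pt: float,
    genotypes: GenotypeTable,
    ld_r2: float = 0.2,
    min_members: int = 10,
    top_p_max: float = 1e-3,
    ld_provider=None,
) -> list[RtQTLSignal]:
    """Greedy peeling of significant variants into independent signals.

    The lowest-p variant tags a signal; all significant variants in LD
    (r^2 >= ld_r2) with the tag join it; repeat on the remainder. Signals
    with fewer than ``min_members`` members or tag p >= ``top_p_max`` drop.
    Ties in tag selection break toward the smaller genomic coordinate.
    """
    sig = [a for a in assoc if a.p <= threshold_pt]
    if not sig:
        return []
    ld = ld_provider or (lambda i, j: genotypes.ld_r2(i, j))
    by_var = {a.variant: a for a in sig}
    remaining = sorted(by_var, key=lambda v: (by_var[v].p, genotypes.pos[v]))
    signals = []
    while remaining:
        tag = remaining[0]
        rem = np.array(remaining)
        r2 = np.atleast_1d(ld(tag, rem))
        members = rem[r2 >= ld_r2]
        if tag not in members:
            members = np.append(members, tag)
        sigl = RtQTLSignal(
            tag=int(tag),
            tag_id=str(genotypes.ids[tag]),
            members=np.sort(members),
            member_p={int(v): by_var[v].p for v in members},
            member_beta={int(v): by_var[v].beta for v in members},
            top_p=by_var[tag].p,
            threshold_pt=threshold_pt,
            chrom=str(genotypes.chrom[tag]),
            window=by_var[tag].window,
            windows={by_var[tag].window},
        )
        signals.append(sigl)
        drop = set(members.tolist())
        remaining = [v for v in remaining if v not in drop]
    kept = [s for s in signals if s.n_members >= min_members and s.top_p < top_p_max]
    return kept


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, i):
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i, j):
        self.p[self.find(i)] = self.find(j)


def consolidate_signals(
    signals: list[RtQTLSignal],
    smoothed: RTMatrix,
    genotypes: GenotypeTable,
    ld_r2: float = 0.2,
    window_r2: float = 0.1,
    dist_max: float = 2_000_000,
) -> list[RtQTLSignal]:
    """Merge the same signal detected in different windows.

    Signals merge when their tag variants are in LD (r^2 >= 0.2), their
    windows' timing profiles are correlated (R^2 >= 0.1), and the windows are
    less than 2 Mb apart.
    """
    if not signals:
        return []
    uf = _UnionFind(len(signals))
    centers = smoothed.grid.centers
    chroms = smoothed.grid.chrom
    for i in range(len(signals)):
        for j in range(i + 1, len(signals)):
            a, b = signals[i], signals[j]
            if str(chroms[a.window]) != str(chroms[b.window]):
                continue
            if abs(centers[a.window] - centers[b.window]) >= dist_max:
                continue
            if genotypes.ld_r2(a.tag, np.array([b.tag]))[0] < ld_r2:
                continue
            x, y = smoothed.values[:, a.window], smoothed.values[:, b.window]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.corrcoef(x[ok], y[ok])[0, 1] ** 2 < window_r2:
                continue
            uf.union(i, j)
    groups: dict[int, list[RtQTLSignal]] = {}
    for i, s in enumerate(signals):
        groups.setdefault(uf.find(i), []).append(s)
    merged = []
    for grp in groups.values():
        best = min(grp, key=lambda s: (s.top_p, genotypes.pos[s.tag]))
        member_p: dict[int, float] = {}
        member_beta: dict[int, float] = {}
        windows: set[int] = set()
        for s in grp:
            windows |= s.windows
            for v, p in s.member_p.items():
                if v not in member_p or p < member_p[v]:
                    member_p[v] = p
                    member_beta[v] = s.member_beta[v]
        merged.append(
            RtQTLSignal(
                tag=best.tag,
                tag_id=best.tag_id,
                members=np.array(sorted(member_p)),
                member_p=member_p,
                member_beta=member_beta,
                top_p=best.top_p,
                threshold_pt=best.threshold_pt,
                chrom=best.chrom,
                window=best.window,
                windows=windows,
                provenance=best.provenance,
                source=best.source,
            )
        )
    merged.sort(key=lambda s: (s.chrom, genotypes.pos[s.tag]))
    return merged


def conditional_split(
    signal: RtQTLSignal,
    smoothed: RTMatrix,
    genotypes: GenotypeTable,
    covariates: CovariateSet | None,
    alpha: float = 0.05,
    ld_r2: float = 0.2,
    max_rounds: int = 4,
) -> list[RtQTLSignal]:
    """Condition on the tag; Bonferroni-significant residual members seed new signals."""
    out = [signal]
    y = smoothed.values[:, signal.window]
    ok = ~np.isnan(y)
    base = covariates.matrix() if covariates is not None else np.ones((len(y), 1))
    tags = [signal.tag]
    for _ in range(max_rounds):
        members = np.array(sorted(set(int(v) for s in out for v in s.members)))
        others = members[~np.isin(members, tags)]
        if len(others) == 0:
            break
        X = np.column_stack([base] + [genotypes.dosages[:, t][:, None] for t in tags])
        Q = _orthonormal(X[ok])
        df = ok.sum() - Q.shape[1] - 1
        if df < 3:
            break
        yr = residualize(y[ok][:, None], Q)[:, 0]
        G = residualize(genotypes.dosages[np.ix_(ok, others)], Q)
        gn = np.sqrt((G**2).sum(axis=0))
        gn[gn == 0] = 1.0
        r = (yr / np.sqrt((yr**2).sum())) @ (G / gn)
        p = corr_pvalues(r, df)
        thresh = alpha / len(members)
        if p.min() >= thresh:
            break
        new_tag = int(others[np.lexsort((genotypes.pos[others], p))[0]])
        sig_set = others[p < thresh]
        r2 = genotypes.ld_r2(new_tag, sig_set)
        new_members = np.sort(sig_set[np.atleast_1d(r2) >= ld_r2])
        out.append(
            RtQTLSignal(
                tag=new_tag,
                tag_id=str(genotypes.ids[new_tag]),
                members=new_members,
                member_p={int(v): signal.member_p.get(int(v), float(p[list(others).index(v)])) for v in new_members},
                member_beta={int(v): signal.member_beta.get(int(v), 0.0) for v in new_members},
                top_p=signal.member_p.get(new_tag, float(p.min())),
                threshold_pt=signal.threshold_pt,
                chrom=signal.chrom,
                window=signal.window,
                windows=set(signal.windows),
                provenance="conditional_split",
                source=signal.source,
            )
        )
        tags.append(new_tag)
    return out


def tag_window_pvalues(
    signal: RtQTLSignal,
    smoothed: RTMatrix,
    genotypes: GenotypeTable,
    covariates: CovariateSet | None,
    matrix_override: RTMatrix | None = None,
) -> np.ndarray:
    """Per-window association p of the signal's tag along its chromosome."""
    mat = matrix_override if matrix_override is not None else smoothed
    sl = mat.grid.chrom_slice(signal.chrom)
    g = genotypes.dosages[:, signal.tag]
    n = len(g)
    base = covariates.matrix() if covariates is not None else np.ones((n, 1))
    pvals = np.full(sl.stop - sl.start, np.nan)
    Y = mat.values[:, sl]
    complete = ~np.isnan(Y).any(axis=0)
    if complete.any():
        Q = _orthonormal(base)
        df = n - Q.shape[1] - 1
        yr = residualize(Y[:, complete], Q)
        gr = residualize(g[:, None], Q)[:, 0]
        yn = np.sqrt((yr**2).sum(axis=0))
        yn[yn == 0] = 1.0
        gn = np.sqrt((gr**2).sum())
        r = (gr @ yr) / (yn * gn)
        pvals[complete] = corr_pvalues(r, df)
    # windows with per-sample missingness: test on the available subset
    for j in np.flatnonzero(~complete):
        y = Y[:, j]
        ok = ~np.isnan(y)
        if ok.sum() < max(10, base.shape[1] + 3):
            continue
        Q = _orthonormal(base[ok])
        df = ok.sum() - Q.shape[1] - 1
        yr = residualize(y[ok][:, None], Q)[:, 0]
        gr = residualize(g[ok][:, None], Q)[:, 0]
        denom = np.sqrt((yr**2).sum() * (gr**2).sum())
        if denom == 0:
            continue
        r = float(yr @ gr / denom)
        pvals[j] = corr_pvalues(np.array([r]), df)[0]
    return pvals


def extend_while_significant(pvals: np.ndarray, start: int, alpha: float = 0.05) -> tuple[int, int]:
    """Bidirectional extension from `start` while p <= alpha; NaN stops.

    Returns the inclusive index range of the associated region.
    """
    lo = hi = int(start)
    while lo - 1 >= 0 and not np.isnan(pvals[lo - 1]) and pvals[lo - 1] <= alpha:
        lo -= 1
    while hi + 1 < len(pvals) and not np.isnan(pvals[hi + 1]) and pvals[hi + 1] <= alpha:
        hi += 1
    return lo, hi


def associated_region(
    signal: RtQTLSignal,
    smoothed: RTMatrix,
    genotypes: GenotypeTable,
    covariates: CovariateSet | None,
    alpha: float = 0.05,
) -> tuple[int, int]:
    """Contiguous window interval over which the tag stays nominally associated.

    Starting from the window most strongly associated with the tag, extend
    bidirectionally until p > alpha.
    """
    sl = smoothed.grid.chrom_slice(signal.chrom)
    pv = tag_window_pvalues(signal, smoothed, genotypes, covariates)
    finite = np.flatnonzero(~np.isnan(pv))
    if len(finite) == 0:
        raise ValueError("no testable windows on the signal chromosome")
    start_local = int(finite[np.argmin(pv[finite])])
    lo, hi = extend_while_significant(pv, start_local, alpha)
    grid = smoothed.grid
    signal.associated_region = (int(grid.start[sl.start + lo]), int(grid.end[sl.start + hi]))
    signal.region_windows = (sl.start + lo, sl.start + hi)
    signal.window = sl.start + start_local
    return signal.associated_region


def evaluate_artifact_criteria(
    raw_pvals: np.ndarray,
    smoothed_pvals: np.ndarray,
    removed_pvals: np.ndarray,
    top_p: float,
    n_region_windows: int,
) -> dict[str, bool]:
    """The CNV-artifact criteria on precomputed per-window tag p-values.

    ``raw_pvals``/``smoothed_pvals`` cover the associated region;
    ``removed_pvals`` covers the region plus its 1 Mb flanks (windows without
    removed data excluded). Orders-of-magnitude comparisons use log10
    differences with strict inequality.
    """
    raw_pvals = np.asarray(raw_pvals, dtype=float)
    raw_pvals = raw_pvals[~np.isnan(raw_pvals)]
    smoothed_pvals = np.asarray(smoothed_pvals, dtype=float)
    smoothed_pvals = smoothed_pvals[~np.isnan(smoothed_pvals)]
    removed_pvals = np.asarray(removed_pvals, dtype=float)
    removed_pvals = removed_pvals[~np.isnan(removed_pvals)]
    verdicts: dict[str, bool] = {}
    verdicts["raw_support_5_windows"] = int((raw_pvals < 0.05).sum()) >= 5
    raw_min = float(raw_pvals.min()) if len(raw_pvals) else 1.0
    smooth_min = float(smoothed_pvals.min()) if len(smoothed_pvals) else 1.0
    verdicts["raw_vs_smoothed_order"] = bool(np.log10(raw_min) > np.log10(smooth_min) - 1.0)
    allowed = 1.0
    if top_p <= 5e-8:
        allowed = 4.0
    elif top_p <= 5e-6:
        allowed = 2.0
    removed_min = float(removed_pvals.min()) if len(removed_pvals) else 1.0
    verdicts["removed_vs_raw_order"] = bool(np.log10(removed_min) > np.log10(raw_min) - allowed)
    max_removed_better = 3 if top_p <= 5e-8 else 2
    verdicts["removed_windows_beating_raw"] = int((removed_pvals < raw_min).sum()) <= max_removed_better
    verdicts["raw_min_p_and_region_size"] = (raw_min < 0.01) and (n_region_windows > 1)
    return verdicts


def artifact_filter(
    signal: RtQTLSignal,
    raw: RTMatrix,
    smoothed: RTMatrix,
    genotypes: GenotypeTable,
    covariates: CovariateSet | None,
    removed_flank: float = 1_000_000,
) -> dict[str, bool]:
    """CNV-artifact screening of one signal; records per-criterion verdicts.

    Criteria (all must pass): (1) the tag associates (p < 0.05) with at least
    five raw-data windows in the associated region; (2) the raw minimum p is
    no more than one order of magnitude below the smoothed minimum p; (3) the
    removed-data minimum p is no more than 1 (2 if top p <= 5e-6, 4 if
    <= 5e-8) orders of magnitude below the raw minimum p; (4) at most two
    (three if top p <= 5e-8) removed-data windows beat the raw minimum p;
    (5) raw minimum p < 0.01 and the region spans more than one window.
    """
    if signal.region_windows is None:
        associated_region(signal, smoothed, genotypes, covariates)
    w0, w1 = signal.region_windows
    grid = smoothed.grid
    sl = grid.chrom_slice(signal.chrom)

    pv_smooth = tag_window_pvalues(signal, smoothed, genotypes, covariates)
    pv_raw = tag_window_pvalues(signal, smoothed, genotypes, covariates, matrix_override=raw)
    region = np.arange(w0 - sl.start, w1 - sl.start + 1)

    # removed-data associations within the region +/- 1 Mb
    removed = RTMatrix(
        grid, raw.removed_values.copy(), state="raw", samples=list(raw.samples)
    )
    lo_bp = grid.start[w0] - removed_flank
    hi_bp = grid.end[w1] + removed_flank
    centers = grid.centers[sl]
    in_flank = (centers >= lo_bp) & (centers <= hi_bp)
    pv_removed = tag_window_pvalues(signal, smoothed, genotypes, covariates, matrix_override=removed)

    verdicts = evaluate_artifact_criteria(
        pv_raw[region], pv_smooth[region], pv_removed[in_flank],
        top_p=signal.top_p, n_region_windows=w1 - w0 + 1,
    )
    signal.filter_verdicts = verdicts
    return verdicts


def genomic_inflation(chi2_stats: np.ndarray) -> float:
    """Genomic control lambda: median observed chi^2 over the analytic chi^2_1 median."""
    chi2_stats = np.asarray(chi2_stats, dtype=float)
    if chi2_stats.size == 0:
        raise ValueError("need at least one chi-square statistic")
    return float(np.median(chi2_stats) / stats.chi2.ppf(0.5, df=1))


def merge_cohorts(
    signals_a: list[RtQTLSignal], signals_b: list[RtQTLSignal]
) -> list[RtQTLSignal]:
    """Merge two cohorts' signals, dropping B-signals already captured in A.

    A B-signal is dropped when one of its member variants has a p-value no
    more than two orders of magnitude above B's top p, also belongs to an
    A-signal, and has the same direction of effect in both cohorts.
    """
    a_membership: dict[str, list[float]] = {}
    for s in signals_a:
        for v in s.members:
            a_membership.setdefault(_vid(s, v), []).append(s.member_beta[int(v)])
    merged = list(signals_a)
    for s in signals_b:
        drop = False
        for v in s.members:
            pv = s.member_p[int(v)]
            if np.log10(pv) > np.log10(s.top_p) + 2:
                continue
            vid = _vid(s, v)
            if vid in a_membership:
                if any(np.sign(b) == np.sign(s.member_beta[int(v)]) for b in a_membership[vid]):
                    drop = True
                    break
        if not drop:
            merged.append(s)
    return merged


def _vid(signal: RtQTLSignal, v) -> str:
    return signal.member_ids[int(v)] if hasattr(signal, "member_ids") else f"{signal.chrom}:{int(v)}"


def attach_variant_ids(signals: list[RtQTLSignal], genotypes: GenotypeTable) -> None:
    """Attach a variant-index -> id map so cohorts can be merged by id."""
    for s in signals:
        s.member_ids = {int(v): str(genotypes.ids[int(v)]) for v in s.members}


def validation_binomial_parameter(n_datasets: int, alpha: float = 0.05) -> float:
    """Chance probability that a signal validates in >= 1 of d datasets: 1-(1-alpha/2)^d."""
    if n_datasets <= 0:
        raise ValueError("need at least one validation dataset")
    return 1.0 - (1.0 - alpha / 2.0) ** n_datasets


def validate_signals(
    signals: list[RtQTLSignal],
    discovery_genotypes: GenotypeTable,
    validation_cohorts: list[tuple[RTMatrix, GenotypeTable, CovariateSet | None]],
    alpha: float = 0.05,
):
    """Test each signal in validation cohorts at the nearest timing locus.

    A signal is "validated" when nominally associated (p < alpha) with the
    same direction of effect in at least one cohort. Signals whose top
    variant (or a fallback member within two orders of magnitude of the top
    p) is absent, non-polymorphic, or allele-inconsistent in every cohort are
    excluded from the denominator. Returns per-signal verdicts and the
    cohort-level binomial p with parameter 1-(1-alpha/2)^d.
    """
    d = len(validation_cohorts)
    param = validation_binomial_parameter(d, alpha)
    verdicts: dict[int, bool | None] = {}
    for i, s in enumerate(signals):
        tested = False
        validated = False
        candidates = [s.tag] + [
            int(v) for v in s.members
            if int(v) != s.tag and np.log10(s.member_p[int(v)]) <= np.log10(s.top_p) + 2
        ]
        for smoothed_v, geno_v, cov_v in validation_cohorts:
            idx_by_id = {str(x): j for j, x in enumerate(geno_v.ids)}
            for cand in candidates:
                vid = str(discovery_genotypes.ids[cand])
                j = idx_by_id.get(vid)
                if j is None:
                    continue
                dos = geno_v.dosages[:, j]
                if not ((dos == 0).any() and (dos == 1).any() and (dos == 2).any()):
                    continue
                va = geno_v.variants.iloc[j]
                da = discovery_genotypes.variants.iloc[cand]
                if str(va["alt"]) != str(da["alt"]) or str(va["ref"]) != str(da["ref"]):
                    continue
                w = smoothed_v.grid.locate(s.chrom, smoothed_v.grid.centers[s.window])
                y = smoothed_v.values[:, w]
                ok = ~np.isnan(y)
                if ok.sum() < 5:
                    continue
                base = cov_v.matrix()[ok] if cov_v is not None else np.ones((ok.sum(), 1))
                Q = _orthonormal(base)
                df = ok.sum() - Q.shape[1] - 1
                yr = residualize(y[ok][:, None], Q)[:, 0]
                gr = residualize(dos[ok][:, None], Q)[:, 0]
                denom = np.sqrt((yr**2).sum() * (gr**2).sum())
                if denom == 0:
                    continue
                r = float(yr @ gr / denom)
                pv = corr_pvalues(np.array([r]), df)[0]
                tested = True
                if pv < alpha and np.sign(r) == np.sign(s.member_beta.get(cand, r)):
                    validated = True
                break
            if validated:
                break
        verdicts[i] = validated if tested else None
    n_tested = sum(1 for v in verdicts.values() if v is not None)
    n_valid = sum(1 for v in verdicts.values() if v)
    if n_tested == 0:
        raise ValueError("no testable signals in the validation cohorts")
    p = stats.binomtest(n_valid, n_tested, param, alternative="greater").pvalue
    return verdicts, float(p), param
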