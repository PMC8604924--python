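"""Replication-timing peaks (initiation-site proxies) and inter-individual
variant regions.

Peaks are per-sample local maxima of the smoothed profile, clustered across
samples by single-linkage agglomerative clustering with a 200 kb distance
cutoff; for 1-D positions this is exactly the partition at consecutive gaps
larger than the cutoff. Variant regions are local maxima of the smoothed
across-sample SD track exceeding the genome-wide mean SD, confirmed by
pairwise t-tests on raw data in 500 kb windows with Bonferroni correction,
then extended, merged or split, and screened for being driven by a handful
of samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .rtmatrix import RTMatrix

log = logging.getLogger(__name__)


def local_extrema(values: np.ndarray, mode: str = "max") -> np.ndarray:
    """Indices of strict local maxima (or minima); plateaus take the leftmost point.

    NaNs break the sequence: a point adjacent to NaN is not an extremum.
    """
    v = values if mode == "max" else -np.asarray(values)
    n = len(v)
    out = []
    i = 1
    while i < n - 1:
        if np.isnan(v[i]) or np.isnan(v[i - 1]):
            i += 1
            continue
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j + 1 < n and not np.isnan(v[j + 1]) and v[j + 1] < v[i]:
                out.append(i)  # leftmost window of the plateau
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


@dataclass
class PeakCluster:
    chrom: str
    center: float
    boundary: tuple[int, int]
    member_samples: dict[int, float]  # sample index -> retained peak position
    support: float

    def __post_init__(self):
        if not 0 < self.support <= 1:
            raise ValueError("support must be in (0, 1]")


def sample_peak_positions(matrix: RTMatrix, mode: str = "max") -> list[tuple[str, float, int]]:
    """(chrom, position, sample) for every per-sample local extremum."""
    grid = matrix.grid
    centers = grid.centers
    out = []
    for chrom in dict.fromkeys(grid.chrom):
        sl = grid.chrom_slice(str(chrom))
        for s in range(matrix.n_samples):
            idx = local_extrema(matrix.values[s, sl], mode=mode)
            for i in idx:
                out.append((str(chrom), float(centers[sl.start + i]), s))
    return out


def _single_linkage_1d(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """Cluster labels for sorted 1-D positions cut at `cutoff` (single linkage)."""
    order = np.argsort(positions, kind="stable")
    labels = np.zeros(len(positions), dtype=int)
    lab = 0
    prev = None
    for i in order:
        if prev is not None and positions[i] - prev > cutoff:
            lab += 1
        labels[i] = lab
        prev = positions[i]
    return labels


def call_peak_clusters(
    matrix: RTMatrix,
    link_dist: float = 200_000,
    min_support: float = 0.10,
    boundary_mode: str = "range",
    mode: str = "max",
) -> list[PeakCluster]:
    """Cluster per-sample peaks across the cohort.

    Within a cluster a sample contributing several peaks keeps only the one
    nearest the cluster center (center recomputed once after pruning).
    Boundary is the full member range ("range") or the 5th-95th percentile
    ("trimmed"). Clusters supported by <= ``min_support`` of samples are
    dropped (strictly more than 10% of samples required at the default).
    """
    if matrix.state != "smoothed":
        raise ValueError("peak calling expects the smoothed matrix")
    peaks = sample_peak_positions(matrix, mode=mode)
    if not peaks:
        warnings.warn("no local extrema found in any sample")
        return []
    clusters: list[PeakCluster] = []
    chroms = np.array([p[0] for p in peaks], dtype=object)
    pos = np.array([p[1] for p in peaks])
    smp = np.array([p[2] for p in peaks])
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        labels = _single_linkage_1d(pos[sel], link_dist)
        cpos, csmp = pos[sel], smp[sel]
        for lab in np.unique(labels):
            m = labels == lab
            p, s = cpos[m], csmp[m]
            center = p.mean()
            members: dict[int, float] = {}
            for si in np.unique(s):
                cand = p[s == si]
                members[int(si)] = float(cand[np.argmin(np.abs(cand - center))])
            kept = np.array(list(members.values()))
            center = float(kept.mean())
            if boundary_mode == "trimmed":
                lo, hi = np.percentile(kept, [5, 95])
            else:
                lo, hi = kept.min(), kept.max()
            support = len(members) / matrix.n_samples
            if support <= min_support:
                continue
            clusters.append(
                PeakCluster(
                    chrom=str(chrom),
                    center=center,
                    boundary=(int(lo), int(hi) + 1),
                    member_samples=members,
                    support=support,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.center))
    return clusters


@dataclass
class VariantRegion:
    chrom: str
    interval: tuple[int, int]
    sd_peak_position: int
    n_significant_pairs: int = 0
    driver_fraction: float = 1.0
    _sd_peak_window: int = field(default=-1, repr=False)

    def __post_init__(self):
        if not self.interval[0] <= self.sd_peak_position <= self.interval[1]:
            raise ValueError("interval must cover the SD peak position")


@dataclass
class VariantCallParams:
    ttest_window: int = 500_000  # centered window for the pairwise t-tests
    alpha: float = 0.05
    extend_step: int = 200_000
    extend_slide: int = 100_000
    extend_frac: float = 0.001  # stop extension below this significant-pair fraction
    merge_corr: float = 0.9
    driver_fraction_max: float = 0.01
    sd_smooth_penalty: float = 25.0


def _pairwise_welch(values: np.ndarray) -> np.ndarray:
    """Welch t-test p-values for all sample pairs; values is (n_samples, n_points).

    Each sample contributes its non-NaN points in the window.
    """
    n = values.shape[0]
    cnt = (~np.isnan(values)).sum(axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        var = np.nanvar(values, axis=1, ddof=1)
    vi = var / cnt
    se2 = vi[:, None] + vi[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean[:, None] - mean[None, :]) / np.sqrt(se2)
        df = se2**2 / (vi[:, None] ** 2 / (cnt[:, None] - 1) + vi[None, :] ** 2 / (cnt[None, :] - 1))
    iu = np.triu_indices(n, k=1)
    p = 2 * stats.t.sf(np.abs(t[iu]), df[iu])
    bad = (cnt[:, None] < 2) | (cnt[None, :] < 2)
    p[bad[iu]] = 1.0
    return p


def _window_pvalues(raw: RTMatrix, chrom: str, lo: float, hi: float) -> np.ndarray:
    grid = raw.grid
    sl = grid.chrom_slice(chrom)
    wsel = np.flatnonzero((grid.centers[sl] >= lo) & (grid.centers[sl] <= hi)) + sl.start
    if len(wsel) == 0:
        return np.ones(raw.n_samples * (raw.n_samples - 1) // 2)
    return _pairwise_welch(raw.values[:, wsel])


def call_rt_variants(
    raw: RTMatrix,
    smoothed: RTMatrix,
    params: VariantCallParams | None = None,
) -> list[VariantRegion]:
    """Call inter-individual replication-timing variant regions.

    See the module docstring for the procedure. The "driven by <=1% of
    samples" rule is operationalized as: if removing the most extreme
    ceil(1%) of samples at the SD peak abolishes the SD-peak criterion
    (SD no longer above the genome-wide mean), the region is removed.
    """
    if raw.n_samples < 2:
        raise ValueError("variant calling needs at least 2 samples")
    params = params or VariantCallParams()
    grid = smoothed.grid
    sd = smoothed.sd_track()
    # smooth the SD track per chromosome with the profile spline
    sd_smooth = np.full_like(sd, np.nan)
    x = grid.centers / grid.window_size
    for chrom in dict.fromkeys(grid.chrom):
        sl = grid.chrom_slice(str(chrom))
        ok = ~np.isnan(sd[sl])
        if ok.sum() < 4:
            continue
        idx = np.flatnonzero(ok) + sl.start
        spl = make_smoothing_spline(x[idx], sd[idx], lam=params.sd_smooth_penalty)
        sd_smooth[idx] = spl(x[idx])
    genome_mean_sd = np.nanmean(sd_smooth)

    candidates = []
    for chrom in dict.fromkeys(grid.chrom):
        sl = grid.chrom_slice(str(chrom))
        for i in local_extrema(sd_smooth[sl], mode="max"):
            w = sl.start + i
            if sd_smooth[w] > genome_mean_sd:
                candidates.append((str(chrom), w))
    if not candidates:
        return []

    n_pairs = raw.n_samples * (raw.n_samples - 1) // 2
    n_tests = n_pairs * len(candidates)
    alpha_bonf = params.alpha / n_tests

    regions: list[VariantRegion] = []
    for chrom, w in candidates:
        center = grid.centers[w]
        p = _window_pvalues(raw, chrom, center - params.ttest_window / 2, center + params.ttest_window / 2)
        n_sig = int((p < alpha_bonf).sum())
        if n_sig == 0:
            continue
        # bidirectional extension in 200 kb windows sliding 100 kb
        lo = center - params.ttest_window / 2
        hi = center + params.ttest_window / 2
        chrom_end = grid.chrom_lengths()[chrom]
        for direction in (-1, +1):
            edge = lo if direction < 0 else hi
            while 0 < edge < chrom_end:
                a = edge - params.extend_step if direction < 0 else edge
                b = edge if direction < 0 else edge + params.extend_step
                pv = _window_pvalues(raw, chrom, a, b)
                if (pv < params.alpha).mean() < params.extend_frac:
                    break
                edge += direction * params.extend_slide
            if direction < 0:
                lo = max(0.0, edge)
            else:
                hi = min(float(chrom_end), edge)
        regions.append(
            VariantRegion(
                chrom=chrom,
                interval=(int(lo), int(hi)),
                sd_peak_position=int(center),
                n_significant_pairs=n_sig,
                _sd_peak_window=w,
            )
        )

    regions = _merge_or_split(regions, smoothed, sd_smooth, params)

    # remove regions driven by <= driver_fraction_max of the samples
    kept = []
    k = int(np.ceil(params.driver_fraction_max * smoothed.n_samples))
    for reg in regions:
        vals = smoothed.values[:, reg._sd_peak_window]
        ok = ~np.isnan(vals)
        v = vals[ok]
        if len(v) <= k + 1:
            continue
        dev = np.abs(v - np.median(v))
        keep_idx = np.argsort(dev)[: len(v) - k]
        sd_trim = v[keep_idx].std(ddof=1)
        reg.driver_fraction = 1.0 if sd_trim > genome_mean_sd else k / smoothed.n_samples
        if sd_trim > genome_mean_sd:
            kept.append(reg)
    return kept


def _merge_or_split(regions, smoothed, sd_smooth, params):
    """Merge overlapping regions whose SD-peak profiles correlate > merge_corr,
    otherwise split them at the intervening SD minimum."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.interval[0]))
    out: list[VariantRegion] = []
    for reg in regions:
        if out and out[-1].chrom == reg.chrom and reg.interval[0] <= out[-1].interval[1]:
            prev = out[-1]
            a = smoothed.values[:, prev._sd_peak_window]
            b = smoothed.values[:, reg._sd_peak_window]
            ok = ~(np.isnan(a) | np.isnan(b))
            corr = np.corrcoef(a[ok], b[ok])[0, 1] if ok.sum() > 2 else 0.0
            if corr > params.merge_corr:
                major = prev if prev.n_significant_pairs >= reg.n_significant_pairs else reg
                out[-1] = VariantRegion(
                    chrom=prev.chrom,
                    interval=(prev.interval[0], max(prev.interval[1], reg.interval[1])),
                    sd_peak_position=major.sd_peak_position,
                    n_significant_pairs=prev.n_significant_pairs + reg.n_significant_pairs,
                    _sd_peak_window=major._sd_peak_window,
                )
            else:
                # split at the SD minimum between the two peaks
                grid = smoothed.grid
                sl = grid.chrom_slice(reg.chrom)
                between = np.flatnonzero(
                    (grid.centers >= prev.sd_peak_position) & (grid.centers <= reg.sd_peak_position)
                    & (grid.chrom == reg.chrom)
                )
                if len(between):
                    valley = between[np.nanargmin(sd_smooth[between])]
                    cut = int(grid.centers[valley])
                else:
                    cut = (prev.interval[1] + reg.interval[0]) // 2
                out[-1] = VariantRegion(
                    chrom=prev.chrom,
                    interval=(prev.interval[0], cut),
                    sd_peak_position=prev.sd_peak_position,
                    n_significant_pairs=prev.n_significant_pairs,
                    _sd_peak_window=prev._sd_peak_window,
                )
                out.append(
                    VariantRegion(
                        chrom=reg.chrom,
                        interval=(cut, reg.interval[1]),
                        sd_peak_position=reg.sd_peak_position,
                        n_significant_pairs=reg.n_significant_pairs,
                        _sd_peak_window=reg._sd_peak_window,
                    )
                )
        else:
            out.append(reg)
    return out


def call_valleys(matrix: RTMatrix, **kwargs) -> list[PeakCluster]:
    """Replication terminus proxies: local minima clustered like peaks."""
    return call_peak_clusters(matrix, mode="min", **kwargs)
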