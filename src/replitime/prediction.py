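"""How well do chromatin-defined regions predict replication initiation sites?

Given a set of predicted regions (typically me3-ac-hyper regions) and the
peak catalogue, this module computes region-to-peak distances (physical and
fractional), permutation baselines from 1-2 Mb random shifts, positive
predictive value and sensitivity at a distance cutoff, and ROC curves built
from sampled peak windows (positives) and windows far from any peak
(negatives).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import GenomeGrid, Intervals

log = logging.getLogger(__name__)


@dataclass
class PeakCatalogue:
    """Peak boundaries plus centers; build from clusters or raw maxima."""

    boundaries: Intervals  # one interval per peak
    centers: list[tuple[str, int]]

    @classmethod
    def from_clusters(cls, clusters) -> "PeakCatalogue":
        ivs = []
        centers = []
        for c in clusters:
            lo, hi = c.boundary
            if hi <= lo:
                hi = lo + 1
            ivs.append((c.chrom, int(lo), int(hi)))
            centers.append((c.chrom, int(c.center)))
        return cls(Intervals.from_records(ivs), centers)

    @classmethod
    def from_maxima(cls, positions: list[tuple[str, int]], halfwidth: int = 100_000) -> "PeakCatalogue":
        """Single-profile mode: boundaries are +/- halfwidth around local maxima."""
        ivs = [(c, max(0, p - halfwidth), p + halfwidth) for c, p in positions]
        return cls(Intervals.from_records(ivs), [(c, int(p)) for c, p in positions])


def distances_to_peaks(
    regions: Intervals, peaks: PeakCatalogue, mode: str = "physical"
) -> np.ndarray:
    """Per-region distance to the nearest peak.

    Physical: 0 for regions overlapping a peak boundary interval, else bp to
    the nearest boundary. Fractional: physical distance divided by half the
    span between the two flanking peak centers (0 at a peak, 1 at the
    midpoint between peaks); chromosome ends use the single flanking span.
    """
    if len(peaks.boundaries) == 0:
        raise ValueError("empty peak catalogue")
    chrom = regions.df["chrom"].to_numpy(dtype=object)
    mids = regions.df[["start", "end"]].mean(axis=1).to_numpy()
    overlap = peaks.boundaries.overlaps_intervals(
        chrom, regions.df["start"].to_numpy(), regions.df["end"].to_numpy()
    )
    dist = peaks.boundaries.distance_to_points(chrom, mids)
    # distance measured from the region edge nearest the peak, not the midpoint
    half_len = (regions.df["end"].to_numpy() - regions.df["start"].to_numpy()) / 2
    dist = np.maximum(dist - half_len, 0.0)
    dist[overlap] = 0.0
    if mode == "physical":
        return dist
    if mode != "fractional":
        raise ValueError("mode must be 'physical' or 'fractional'")
    centers_by_chrom: dict[str, np.ndarray] = {}
    for c, p in peaks.centers:
        centers_by_chrom.setdefault(c, [])
    for c, p in peaks.centers:
        centers_by_chrom[c].append(p)
    centers_by_chrom = {c: np.sort(v) for c, v in centers_by_chrom.items()}
    out = np.zeros(len(dist))
    for i, (c, m) in enumerate(zip(chrom, mids)):
        if dist[i] == 0:
            continue
        cs = centers_by_chrom.get(str(c))
        if cs is None or len(cs) == 0:
            out[i] = np.nan
            continue
        j = np.searchsorted(cs, m)
        if 0 < j < len(cs):
            span = (cs[j] - cs[j - 1]) / 2
        elif j == 0:
            span = (cs[1] - cs[0]) / 2 if len(cs) > 1 else cs[0]
        else:
            span = (cs[-1] - cs[-2]) / 2 if len(cs) > 1 else cs[-1]
        out[i] = min(dist[i] / span, 1.0) if span > 0 else 1.0
    return out


def shift_regions(
    regions: Intervals,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    shift_range: tuple[int, int] = (1_000_000, 2_000_000),
) -> tuple[Intervals, np.ndarray]:
    """Shift each region by a random 1-2 Mb offset (random sign), reflecting
    at chromosome ends so regions stay on-chromosome."""
    recs = []
    mags = []
    for row in regions.df.itertuples(index=False):
        length = chrom_lengths[str(row.chrom)]
        if length < 2 * shift_range[1]:
            raise ValueError(f"chromosome {row.chrom} shorter than twice the maximum shift")
        mag = rng.uniform(*shift_range)
        shift = rng.choice([-1.0, 1.0]) * mag
        s, e = row.start + shift, row.end + shift
        if s < 0 or e > length:
            shift = -shift
            s, e = row.start + shift, row.end + shift
        mags.append(abs(shift))
        recs.append((row.chrom, int(max(0, s)), int(min(length, e))))
    return Intervals.from_records(recs), np.asarray(mags)


def shift_permutation_baseline(
    regions: Intervals,
    peaks: PeakCatalogue,
    chrom_lengths: dict[str, int],
    n_perm: int = 100,
    shift_range: tuple[int, int] = (1_000_000, 2_000_000),
    mode: str = "physical",
    seed: int = 0,
) -> dict:
    """Null distance distribution from shifted regions.

    Returns the pooled null distances, the fold-improvement of the observed
    median over the null median, and a one-sided Wilcoxon rank-sum p-value
    for observed distances being smaller than the null.
    """
    rng = np.random.default_rng(seed)
    observed = distances_to_peaks(regions, peaks, mode=mode)
    null = []
    for _ in range(n_perm):
        shifted, _ = shift_regions(regions, chrom_lengths, rng, shift_range)
        null.append(distances_to_peaks(shifted, peaks, mode=mode))
    null = np.concatenate(null)
    obs_med = float(np.median(observed))
    null_med = float(np.median(null))
    fold = null_med / obs_med if obs_med > 0 else np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.mannwhitneyu(observed, null, alternative="less").pvalue)
    return dict(
        observed=observed, null=null, observed_median=obs_med,
        null_median=null_med, fold_improvement=fold, wilcoxon_p=p,
    )


def ppv_sensitivity(
    regions: Intervals,
    peaks: PeakCatalogue,
    cutoff: int = 10_000,
    baseline: dict | None = None,
    chrom_lengths: dict[str, int] | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """PPV and sensitivity at a distance cutoff, with a shift-permutation Z test.

    PPV: fraction of predicted regions within ``cutoff`` of a peak boundary.
    Sensitivity: fraction of peaks whose boundary lies within ``cutoff`` of a
    predicted region.
    """
    d_regions = distances_to_peaks(regions, peaks, mode="physical")
    ppv = float((d_regions <= cutoff).mean())
    sens = float(_peak_recall(regions, peaks, cutoff))
    out = dict(ppv=ppv, sensitivity=sens, cutoff=cutoff)
    if baseline is None and chrom_lengths is not None:
        rng = np.random.default_rng(seed)
        null_ppv, null_sens = [], []
        for _ in range(n_perm):
            shifted, _ = shift_regions(regions, chrom_lengths, rng)
            null_ppv.append((distances_to_peaks(shifted, peaks) <= cutoff).mean())
            null_sens.append(_peak_recall(shifted, peaks, cutoff))
        baseline = dict(ppv=np.asarray(null_ppv), sensitivity=np.asarray(null_sens))
    if baseline is not None:
        for key in ("ppv", "sensitivity"):
            null = np.asarray(baseline[key])
            sd = null.std(ddof=1)
            z = (out[key] - null.mean()) / sd if sd > 0 else 0.0
            out[f"{key}_null_mean"] = float(null.mean())
            out[f"{key}_z"] = float(z)
            out[f"{key}_p"] = float(stats.norm.sf(z))
    return out


def _peak_recall(regions: Intervals, peaks: PeakCatalogue, cutoff: int) -> float:
    hits = 0
    df = peaks.boundaries.df
    for row in df.itertuples(index=False):
        mid = (row.start + row.end) / 2
        d = regions.distance_to_points([row.chrom], [mid])[0]
        d = max(0.0, d - (row.end - row.start) / 2)
        if d <= cutoff:
            hits += 1
    return hits / len(df)


def roc_curve(
    regions: Intervals,
    grid: GenomeGrid,
    peaks: PeakCatalogue,
    n_pos: int = 1000,
    n_neg: int = 1000,
    neg_min_dist: int = 750_000,
    cutoff_grid: np.ndarray | None = None,
    analyzable: np.ndarray | None = None,
    seed: int = 0,
) -> dict:
    """ROC of "is this window a replication-timing peak?" from region proximity.

    Positives: windows at peaks (overlapping a peak boundary). Negatives:
    windows farther than ``neg_min_dist`` from the nearest peak center.
    A window is called "peak" when its center lies within the cutoff distance
    of a predicted region; TPR/FPR traced over the cutoff grid, AUC by
    trapezoid. Sampling is without replacement; short classes shrink the
    sample with a warning.
    """
    rng = np.random.default_rng(seed)
    centers = grid.centers
    chrom = grid.chrom
    ok = np.ones(grid.n_windows, dtype=bool) if analyzable is None else np.asarray(analyzable)
    pos_mask = peaks.boundaries.overlaps_points(chrom, centers.astype(np.int64)) & ok
    peak_centers = Intervals.from_records([(c, p, p + 1) for c, p in peaks.centers])
    dist_to_peak = peak_centers.distance_to_points(chrom, centers)
    neg_mask = (dist_to_peak > neg_min_dist) & ok & ~pos_mask
    pos_idx = np.flatnonzero(pos_mask)
    neg_idx = np.flatnonzero(neg_mask)
    if len(neg_idx) == 0:
        raise ValueError("no eligible negative windows")
    if len(pos_idx) < n_pos:
        warnings.warn(f"only {len(pos_idx)} positive windows available (wanted {n_pos})")
        n_pos = len(pos_idx)
    if len(neg_idx) < n_neg:
        warnings.warn(f"only {len(neg_idx)} negative windows available (wanted {n_neg})")
        n_neg = len(neg_idx)
    pos = rng.choice(pos_idx, size=n_pos, replace=False)
    neg = rng.choice(neg_idx, size=n_neg, replace=False)
    d_pos = regions.distance_to_points(chrom[pos], centers[pos])
    d_neg = regions.distance_to_points(chrom[neg], centers[neg])
    if cutoff_grid is None:
        cutoff_grid = np.unique(
            np.concatenate([[0], np.geomspace(1_000, 5_000_000, 40), [np.inf]])
        )
    tpr = np.array([(d_pos <= c).mean() for c in cutoff_grid])
    fpr = np.array([(d_neg <= c).mean() for c in cutoff_grid])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return dict(cutoffs=cutoff_grid, tpr=tpr, fpr=fpr, auc=auc, n_pos=n_pos, n_neg=n_neg)


def plot_roc(result: dict, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(result["fpr"], result["tpr"], marker=".", lw=1)
    ax.plot([0, 1], [0, 1], "k--", lw=0.6)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {result['auc']:.3f}")
    return ax
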