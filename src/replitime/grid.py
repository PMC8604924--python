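"""Genomic grids and interval algebra.

Coordinates are 0-based, half-open throughout; BED is the on-disk format.
The grid is the fixed tiling of each chromosome into constant-size,
non-overlapping windows that all replication-timing matrices share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)


class Intervals:
    """A set of intervals on one or more chromosomes with overlap/merge/distance algebra.

    Stored per chromosome as sorted (starts, ends) arrays. Half-open.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        # df columns: chrom, start, end (+ optional extras preserved)
        if df is None:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
        df = df.reset_index(drop=True)
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValueError("intervals must have end > start")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            self._by_chrom[str(chrom)] = (
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
            )

    @classmethod
    def from_records(cls, records) -> "Intervals":
        """records: iterable of (chrom, start, end)."""
        recs = list(records)
        return cls(pd.DataFrame(recs, columns=["chrom", "start", "end"]))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Interval(str(row.chrom), int(row.start), int(row.end))

    @property
    def chroms(self):
        return list(self._by_chrom)

    def merged(self, gap: int = 0) -> "Intervals":
        """Union of intervals, joining any that overlap or lie within `gap` bp."""
        out = []
        for chrom, (starts, ends) in self._by_chrom.items():
            cur_s, cur_e = None, None
            for s, e in zip(starts, ends):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e + gap:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append((chrom, cur_s, cur_e))
        return Intervals.from_records(out)

    def intersect(self, other: "Intervals") -> "Intervals":
        """Base-pair intersection of two interval sets (merged output)."""
        a, b = self.merged(), other.merged()
        out = []
        for chrom in a.chroms:
            if chrom not in b._by_chrom:
                continue
            s1, e1 = a._by_chrom[chrom]
            s2, e2 = b._by_chrom[chrom]
            i = j = 0
            while i < len(s1) and j < len(s2):
                lo = max(s1[i], s2[j])
                hi = min(e1[i], e2[j])
                if lo < hi:
                    out.append((chrom, int(lo), int(hi)))
                if e1[i] < e2[j]:
                    i += 1
                else:
                    j += 1
        return Intervals.from_records(out)

    def overlaps_points(self, chrom: np.ndarray | list, pos: np.ndarray) -> np.ndarray:
        """Boolean array: is each (chrom, pos) point inside some interval?"""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        m = self.merged()
        for c, (starts, ends) in m._by_chrom.items():
            sel = chrom == c
            if not sel.any():
                continue
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = pos[sel][ok] < ends[idx[ok]]
            out[sel] = hit
        return out

    def overlaps_intervals(self, chrom, starts, ends) -> np.ndarray:
        """Boolean array: does each query interval intersect some interval (>=1 bp)?"""
        chrom = np.asarray(chrom, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts), dtype=bool)
        m = self.merged()
        for c, (ms, me) in m._by_chrom.items():
            sel = chrom == c
            if not sel.any():
                continue
            qs, qe = starts[sel], ends[sel]
            # interval [qs,qe) intersects some [ms,me) iff exists i: ms < qe and me > qs
            i = np.searchsorted(me, qs, side="right")  # first interval with me > qs
            hit = (i < len(ms)) & (np.where(i < len(ms), ms[np.minimum(i, len(ms) - 1)], 0) < qe)
            out[sel] = hit
        return out

    def distance_to_points(self, chrom, pos) -> np.ndarray:
        """Distance in bp from each point to the nearest interval (0 if inside)."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.float64)
        out = np.full(len(pos), np.inf)
        m = self.merged()
        for c, (ms, me) in m._by_chrom.items():
            sel = chrom == c
            if not sel.any():
                continue
            p = pos[sel]
            i = np.searchsorted(ms, p, side="right") - 1
            d = np.full(p.shape, np.inf)
            ok = i >= 0
            inside = ok & (p < me[np.maximum(i, 0)])
            d[inside] = 0.0
            left = ok & ~inside
            d[left] = p[left] - me[i[left]]  # bp past the interval end coordinate
            j = np.minimum(i + 1, len(ms) - 1)
            has_next = (i + 1) < len(ms)
            d_next = np.where(has_next, ms[j] - p, np.inf)
            out[sel] = np.minimum(d, np.maximum(d_next, 0))
        return out


@dataclass
class GenomeGrid:
    """Ordered, non-overlapping constant-size windows tiling each chromosome."""

    windows: pd.DataFrame  # columns: chrom, start, end (sorted)
    gaps: Intervals = field(default_factory=Intervals)

    def __post_init__(self):
        w = self.windows.reset_index(drop=True)
        sizes = (w["end"] - w["start"]).unique()
        if len(sizes) != 1:
            raise ValueError("grid windows must have constant size")
        for chrom, sub in w.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if (np.diff(s) <= 0).any() or (s[1:] < e[:-1]).any():
                raise ValueError(f"windows on {chrom} must be sorted and non-overlapping")
        self.windows = w
        self._chrom = w["chrom"].to_numpy(dtype=object)
        self._start = w["start"].to_numpy(dtype=np.int64)
        self._end = w["end"].to_numpy(dtype=np.int64)

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], window_size: int) -> "GenomeGrid":
        recs = []
        for chrom, length in chrom_lengths.items():
            if length % window_size:
                raise ValueError("window_size must divide chromosome length")
            for s in range(0, length, window_size):
                recs.append((chrom, s, s + window_size))
        return cls(pd.DataFrame(recs, columns=["chrom", "start", "end"]))

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def window_size(self) -> int:
        return int(self._end[0] - self._start[0])

    @property
    def chrom(self) -> np.ndarray:
        return self._chrom

    @property
    def start(self) -> np.ndarray:
        return self._start

    @property
    def end(self) -> np.ndarray:
        return self._end

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self._start + self._end)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self._chrom == chrom)
        if len(idx) == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_lengths(self) -> dict[str, int]:
        out = {}
        for chrom in pd.unique(self._chrom):
            sl = self.chrom_slice(str(chrom))
            out[str(chrom)] = int(self._end[sl][-1])
        return out

    def locate(self, chrom: str, pos: float) -> int:
        """Index of the window containing (or nearest to) the position on its chromosome."""
        sl = self.chrom_slice(chrom)
        centers = self.centers[sl]
        return int(sl.start + np.argmin(np.abs(centers - pos)))
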