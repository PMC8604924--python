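"""Named sets of genomic interval tracks (histone marks, TF binding, peaks).

A track set maps mark name -> {sample -> Intervals}. Pooled (sample-less)
tracks use the key ``None``; ``union(mark)`` merges all samples' intervals,
mirroring the use of unioned peak calls across cell lines in cohort-level
enrichment analyses.
"""

from __future__ import annotations

import pandas as pd

from .grid import Intervals


class IntervalTrackSet:
    def __init__(self, tracks: dict[str, dict[str | None, Intervals]] | None = None):
        self._tracks: dict[str, dict[str | None, Intervals]] = tracks or {}

    @property
    def marks(self) -> list[str]:
        return list(self._tracks)

    def samples(self, mark: str) -> list[str | None]:
        return list(self._tracks[mark])

    def add(self, mark: str, intervals: Intervals, sample: str | None = None) -> None:
        self._tracks.setdefault(mark, {})[sample] = intervals

    def get(self, mark: str, sample: str | None = None) -> Intervals:
        return self._tracks[mark][sample]

    def has(self, mark: str, sample: str | None = None) -> bool:
        return mark in self._tracks and sample in self._tracks[mark]

    def union(self, mark: str) -> Intervals:
        """Merged union of the mark's intervals across all samples."""
        frames = [iv.df[["chrom", "start", "end"]] for iv in self._tracks[mark].values() if len(iv)]
        if not frames:
            return Intervals()
        return Intervals(pd.concat(frames, ignore_index=True)).merged()

    def __contains__(self, mark: str) -> bool:
        return mark in self._tracks

    def __len__(self) -> int:
        return len(self._tracks)
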