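"""The replication-timing matrix container.

An RTMatrix holds samples x windows values on a GenomeGrid in one of three
states: ``raw`` copy-number estimates, ``filtered_raw`` (global windows and
per-sample outlier points masked), and ``smoothed`` (Z-normalized, spline
smoothed). Masked values are NaN in ``values`` but the original copy-number
numbers are retained in ``removed_values`` — the rtQTL artifact filter tests
associations on exactly those removed data points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GenomeGrid

STATES = ("raw", "filtered_raw", "smoothed")


@dataclass
class RTMatrix:
    grid: GenomeGrid
    values: np.ndarray  # (n_samples, n_windows), NaN where masked
    state: str = "raw"
    samples: list[str] | None = None
    global_mask: np.ndarray | None = None  # (n_windows,) True = removed for all samples
    removed_values: np.ndarray | None = None  # (n_samples, n_windows), NaN except where masked

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_windows:
            raise ValueError("values must be (n_samples, n_windows) on the grid")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        if self.samples is None:
            self.samples = [f"S{i:04d}" for i in range(self.values.shape[0])]
        if self.global_mask is None:
            self.global_mask = np.zeros(self.grid.n_windows, dtype=bool)
        if self.removed_values is None:
            self.removed_values = np.full_like(self.values, np.nan)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def point_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self, **overrides) -> "RTMatrix":
        kw = dict(
            grid=self.grid,
            values=self.values.copy(),
            state=self.state,
            samples=list(self.samples),
            global_mask=self.global_mask.copy(),
            removed_values=self.removed_values.copy(),
        )
        kw.update(overrides)
        return RTMatrix(**kw)

    def window_medians(self) -> np.ndarray:
        """Across-sample median per window (NaN-aware)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(self.values, axis=0)

    def sd_track(self) -> np.ndarray:
        """Across-sample SD per window (NaN-aware)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.values, axis=0, ddof=1)

    def mask_windows(self, idx: np.ndarray) -> None:
        """Globally mask windows, retaining the raw values in removed_values."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        keep = self.removed_values[:, idx]
        vals = self.values[:, idx]
        self.removed_values[:, idx] = np.where(np.isnan(keep), vals, keep)
        self.values[:, idx] = np.nan
        self.global_mask[idx] = True

    def mask_points(self, mask: np.ndarray) -> None:
        """Mask individual (sample, window) points, retaining values."""
        mask = np.asarray(mask, dtype=bool) & ~np.isnan(self.values)
        self.removed_values[mask] = self.values[mask]
        self.values[mask] = np.nan
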