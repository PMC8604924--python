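import numpy as np
import pandas as pd
import pytest

from replitime.grid import GenomeGrid
from replitime.rtmatrix import RTMatrix
from replitime.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with three planted rtQTLs, shared across tests."""
    config = CohortConfig(
        n_samples=40,
        chrom_length=20_000_000,
        n_rtqtls=3,
        maf_range=(0.2, 0.4),
        variant_spacing=5_000,
        seed=5,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def profiled(small_cohort):
    """(filtered_raw, smoothed) matrices of the small cohort."""
    from replitime.profiles import (
        filter_points_per_sample,
        filter_windows_global,
        normalize_and_smooth,
    )

    filtered = filter_windows_global(small_cohort.depth)
    filtered_raw = filter_points_per_sample(filtered)
    smoothed = normalize_and_smooth(filtered_raw)
    return filtered_raw, smoothed


def make_grid(n_windows: int = 100, window_size: int = 10_000, chrom: str = "chr1") -> GenomeGrid:
    recs = [(chrom, i * window_size, (i + 1) * window_size) for i in range(n_windows)]
    return GenomeGrid(pd.DataFrame(recs, columns=["chrom", "start", "end"]))


def make_matrix(values, state="raw", **kw) -> RTMatrix:
    values = np.asarray(values, dtype=float)
    grid = make_grid(n_windows=values.shape[1], **kw)
    return RTMatrix(grid, values, state=state)
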