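"""Biallelic genotype tables: dosages, QC, and LD.

Dosages count alternative alleles (0/1/2). LD (r²) is the squared Pearson
correlation between dosage vectors, computed from the cohort itself by
default; a reference-panel provider can be plugged in wherever an
``ld_provider`` argument is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeTable:
    """variants: DataFrame with columns chrom, pos, id, ref, alt (sorted by chrom, pos).
    dosages: (n_samples, n_variants) array of alternative-allele counts."""

    variants: pd.DataFrame
    dosages: np.ndarray
    samples: list[str] | None = None

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns must match variant rows")
        if self.samples is None:
            self.samples = [f"S{i:04d}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def pos(self) -> np.ndarray:
        return self.variants["pos"].to_numpy(dtype=np.int64)

    @property
    def chrom(self) -> np.ndarray:
        return self.variants["chrom"].to_numpy(dtype=object)

    @property
    def ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy(dtype=object)

    def maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def allele_freq(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def hwe_p(self) -> np.ndarray:
        """Chi-squared (1 df) Hardy-Weinberg test p-value per variant."""
        n = self.n_samples
        n_het = (self.dosages == 1).sum(axis=0)
        n_alt = (self.dosages == 2).sum(axis=0)
        p = self.allele_freq()
        exp = np.stack([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
        obs = np.stack([n - n_het - n_alt, n_het, n_alt]).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=0)
        return stats.chi2.sf(chi2, df=1)

    def has_all_genotype_classes(self) -> np.ndarray:
        d = self.dosages
        return ((d == 0).any(axis=0)) & ((d == 1).any(axis=0)) & ((d == 2).any(axis=0))

    def qc_mask(self, maf_min: float = 0.05, hwe_p_min: float = 1e-3) -> np.ndarray:
        """Mapping QC: MAF >= 5%, HWE p >= 1e-3, all three genotype classes observed.

        Variants are biallelic by construction of this table."""
        return (
            (self.maf() >= maf_min)
            & (self.hwe_p() >= hwe_p_min)
            & self.has_all_genotype_classes()
        )

    def subset(self, mask_or_idx) -> "GenotypeTable":
        idx = np.flatnonzero(mask_or_idx) if np.asarray(mask_or_idx).dtype == bool else np.asarray(mask_or_idx)
        return GenotypeTable(
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
            samples=self.samples,
        )

    def cis_index(self, chrom: str, center: float, radius: float = 1_000_000) -> np.ndarray:
        """Indices of variants within `radius` bp of a position on `chrom`."""
        sel = (self.chrom == chrom) & (np.abs(self.pos - center) <= radius)
        return np.flatnonzero(sel)

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (mean 0, SD 1); monomorphic columns -> 0."""
        d = self.dosages
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (d - mu) / sd

    def ld_r2(self, i: int, j: np.ndarray | int) -> np.ndarray | float:
        """r² between variant i and variant(s) j from cohort dosages."""
        x = self.dosages[:, i]
        y = self.dosages[:, j]
        xs = x - x.mean()
        ys = y - y.mean(axis=0)
        denom = np.sqrt((xs**2).sum() * (ys**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, (xs @ ys) / denom, 0.0)
        return r**2

    def ld_partner_count(self, r2_min: float = 0.2, radius: float = 1_000_000) -> np.ndarray:
        """Per-variant count of other variants with r² >= r2_min within `radius` bp."""
        counts = np.zeros(self.n_variants, dtype=np.int64)
        z = self.standardized()
        n = self.n_samples
        chunk = 512
        for lo in range(0, self.n_variants, chunk):
            hi = min(lo + chunk, self.n_variants)
            # candidate partners: same chromosome, within radius of any variant in chunk
            c0, c1 = self.chrom[lo], self.chrom[hi - 1]
            lo_pos, hi_pos = self.pos[lo] - radius, self.pos[hi - 1] + radius
            cand = np.flatnonzero(
                ((self.chrom == c0) & (self.pos >= lo_pos) & (self.pos <= hi_pos))
                | ((self.chrom == c1) & (self.pos >= lo_pos) & (self.pos <= hi_pos))
            )
            r = (z[:, lo:hi].T @ z[:, cand]) / n
            r2 = r**2
            in_range = (
                (self.chrom[cand][None, :] == self.chrom[lo:hi][:, None])
                & (np.abs(self.pos[cand][None, :] - self.pos[lo:hi][:, None]) <= radius)
            )
            hits = (r2 >= r2_min) & in_range
            counts[lo:hi] = hits.sum(axis=1) - 1  # exclude self
        return counts


def flip_alleles(table: GenotypeTable, idx: np.ndarray) -> GenotypeTable:
    """Swap ref/alt coding for the given variants (dosage -> 2 - dosage)."""
    v = table.variants.copy()
    d = table.dosages.copy()
    ref = v.loc[idx, "ref"].copy()
    v.loc[idx, "ref"] = v.loc[idx, "alt"].values
    v.loc[idx, "alt"] = ref.values
    d[:, idx] = 2 - d[:, idx]
    return GenotypeTable(v, d, samples=table.samples)
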