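"""The RtQTLModel / RtQTLResults pair.

``RtQTLModel`` bundles a smoothed timing matrix, a QC'd genotype table and
the covariate set, and ``fit()`` runs the full two-step mapping: a
vectorized genome-wide window scan with adaptive permutations, BH selection
of significant windows, per-window empirical FDR thresholds, greedy LD
peeling into signals, consolidation, conditional splitting, associated
regions and the CNV-artifact filters. The returned ``RtQTLResults`` carries
window results, signals, and diagnostic accessors.

The permutation null shares one set of sample permutation orders (drawn once
from the model seed) across windows, so the scan reduces to a handful of
matrix products per chromosome chunk; each window's marginal null
distribution is unaffected by the sharing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable
from .mapping import (
    AssociationResult,
    CovariateSet,
    PermutationPolicy,
    RtQTLSignal,
    WindowResult,
    _orthonormal,
    artifact_filter,
    associated_region,
    attach_variant_ids,
    conditional_split,
    consolidate_signals,
    corr_pvalues,
    define_signals,
    fit_beta_null,
    genomic_inflation,
    genotype_pcs,
    phenotype_pcs,
    residualize,
    significant_windows,
    variant_threshold,
)
from .rtmatrix import RTMatrix

log = logging.getLogger(__name__)


class RtQTLModel:
    """cis-rtQTL mapping model.

    Parameters
    ----------
    smoothed : RTMatrix
        Smoothed timing profiles (the mapping phenotype).
    genotypes : GenotypeTable
        Cohort genotypes; QC (MAF >= 5%, HWE p >= 1e-3, all three genotype
        classes) is applied here unless ``qc=False``.
    raw : RTMatrix, optional
        Filtered raw data; enables the artifact filters and phenotype PCs
        computed the way the mapping pipeline expects.
    n_phenotype_pcs : int
        Number of phenotype PCs in the covariate set (select with
        :func:`select_phenotype_pcs` when unsure).
    """

    def __init__(
        self,
        smoothed: RTMatrix,
        genotypes: GenotypeTable,
        raw: RTMatrix | None = None,
        covariates: CovariateSet | None = None,
        n_genotype_pcs: int = 3,
        n_phenotype_pcs: int = 3,
        cis_radius: float = 1_000_000,
        qc: bool = True,
        maf_min: float = 0.05,
        hwe_p_min: float = 1e-3,
        ld_r2: float = 0.2,
        min_members: int = 10,
        top_p_max: float = 1e-3,
        window_fdr: float = 0.10,
        variant_fdr: float = 0.10,
        variant_perm: int = 500,
        perm_policy: PermutationPolicy | None = None,
    ):
        if smoothed.state != "smoothed":
            raise ValueError("mapping expects the smoothed matrix")
        self.smoothed = smoothed
        self.raw = raw
        self.genotypes_all = genotypes
        if qc:
            mask = genotypes.qc_mask(maf_min=maf_min, hwe_p_min=hwe_p_min)
            self.genotypes = genotypes.subset(mask)
            log.info("genotype QC kept %d/%d variants", self.genotypes.n_variants, genotypes.n_variants)
        else:
            self.genotypes = genotypes
        n = smoothed.n_samples
        if covariates is None:
            gpc = genotype_pcs(self.genotypes, n_genotype_pcs) if n_genotype_pcs else np.empty((n, 0))
            src = raw if raw is not None else smoothed
            ppc = phenotype_pcs(src, n_phenotype_pcs) if n_phenotype_pcs else np.empty((n, 0))
            covariates = CovariateSet(genotype_pcs=gpc, phenotype_pcs=ppc)
        self.covariates = covariates
        if self.covariates.n_columns + 2 >= n:
            raise ValueError("too many covariates for the sample size")
        self.cis_radius = float(cis_radius)
        self.ld_r2 = ld_r2
        self.min_members = min_members
        self.top_p_max = top_p_max
        self.window_fdr = window_fdr
        self.variant_fdr = variant_fdr
        self.variant_perm = variant_perm
        self.perm_policy = perm_policy or PermutationPolicy()

    # -- internals ---------------------------------------------------------

    def _prepare(self):
        sm = self.smoothed
        n = sm.n_samples
        Q = _orthonormal(self.covariates.matrix())
        self._Q = Q
        self._df = n - Q.shape[1] - 1
        complete = ~np.isnan(sm.values).any(axis=0)
        self._windows = np.flatnonzero(complete)
        Y = sm.values[:, self._windows].T  # (n_w, n)
        Yr = Y - (Y @ Q) @ Q.T
        norm = np.sqrt((Yr**2).sum(axis=1, keepdims=True))
        norm[norm == 0] = 1.0
        self._Yu = Yr / norm
        G = residualize(self.genotypes.dosages, Q)
        gnorm = np.sqrt((G**2).sum(axis=0, keepdims=True))
        gnorm[gnorm == 0] = 1.0
        self._Gu = G / gnorm
        self._g_sd = self.genotypes.dosages.std(axis=0)
        self._y_sd = Yr.std(axis=1)

    def _chunks(self, window_list: np.ndarray, size: int = 64):
        """Yield (window indices chunk, cis variant index range) per chromosome."""
        grid = self.smoothed.grid
        geno = self.genotypes
        for chrom in dict.fromkeys(grid.chrom):
            sel = window_list[grid.chrom[window_list] == chrom]
            for lo in range(0, len(sel), size):
                chunk = sel[lo : lo + size]
                c0 = grid.centers[chunk[0]] - self.cis_radius
                c1 = grid.centers[chunk[-1]] + self.cis_radius
                vsel = np.flatnonzero(
                    (geno.chrom == chrom) & (geno.pos >= c0) & (geno.pos <= c1)
                )
                yield chunk, vsel

    def _cis_mask(self, chunk: np.ndarray, vsel: np.ndarray) -> np.ndarray:
        centers = self.smoothed.grid.centers[chunk]
        pos = self.genotypes.pos[vsel]
        return np.abs(pos[None, :] - centers[:, None]) <= self.cis_radius

    def _residualize_perms(self, M: np.ndarray) -> np.ndarray:
        """Re-residualize permuted phenotype rows on the covariates and
        re-normalize: permutation breaks orthogonality to the covariate
        space, which would otherwise deflate the null correlations."""
        Q = self._Q
        M = M - (M @ Q) @ Q.T
        norm = np.sqrt((M**2).sum(axis=1, keepdims=True))
        norm[norm == 0] = 1.0
        return M / norm

    def _scan_windows(self, seed: int) -> list[WindowResult]:
        """Genome-wide window-level scan with adaptive shared permutations."""
        policy = self.perm_policy
        rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
        n = self.smoothed.n_samples
        orders = np.argsort(rng.random((policy.cap, n)), axis=1)
        pos_in_Yu = {w: i for i, w in enumerate(self._windows)}
        results: list[WindowResult] = []
        for chunk, vsel in self._chunks(self._windows):
            if len(vsel) == 0:
                for w in chunk:
                    log.info("window %d: no cis variants, skipped", w)
                continue
            rows = np.array([pos_in_Yu[w] for w in chunk])
            Wc = self._Yu[rows]  # (k, n)
            Gs = self._Gu[:, vsel]  # (n, m)
            mask = self._cis_mask(chunk, vsel)  # (k, m)
            n_cis = mask.sum(axis=1)
            obs_r = Wc @ Gs
            obs_abs = np.where(mask, np.abs(obs_r), -np.inf)
            best_col = obs_abs.argmax(axis=1)
            obs_max_r = obs_abs[np.arange(len(chunk)), best_col]
            active = n_cis > 0
            exceed = np.zeros(len(chunk), dtype=int)
            done = np.zeros(len(chunk), dtype=int)
            null_store: list[list[np.ndarray]] = [[] for _ in chunk]
            offset = 0
            for b in policy.batches:
                idx = np.flatnonzero(active)
                if len(idx) == 0:
                    break
                sub = orders[offset : offset + b]
                # permute sample order of the active windows' phenotypes
                for p0 in range(0, b, 64):
                    block = sub[p0 : p0 + 64]
                    P = Wc[idx][:, block]  # (k_a, nb, n): permuted phenotype copies
                    k_a, nb = P.shape[0], P.shape[1]
                    Pf = self._residualize_perms(P.reshape(k_a * nb, n))
                    R = np.abs(Pf @ Gs).reshape(k_a, nb, -1)
                    R = np.where(mask[idx][:, None, :], R, -np.inf).max(axis=2)
                    for j, wi in enumerate(idx):
                        null_store[wi].append(R[j])
                        exceed[wi] += int((R[j] >= obs_max_r[wi]).sum())
                done[idx] += b
                offset += b
                active &= exceed < policy.min_exceedances
            for j, w in enumerate(chunk):
                if n_cis[j] == 0:
                    continue
                null_r = np.concatenate(null_store[j])
                null_min_p = corr_pvalues(null_r, self._df)
                obs_min_p = float(corr_pvalues(np.array([obs_max_r[j]]), self._df)[0])
                results.append(
                    WindowResult(
                        window=int(w),
                        min_p_nominal=obs_min_p,
                        window_p=fit_beta_null(null_min_p, obs_min_p),
                        n_cis_variants=int(n_cis[j]),
                        best_variant=int(vsel[best_col[j]]),
                        n_perm_used=int(done[j]),
                    )
                )
        return results

    def _variant_stage(self, sig_windows: list[int], seed: int) -> list[RtQTLSignal]:
        """Per-window empirical thresholds and greedy signal definition."""
        rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
        n = self.smoothed.n_samples
        orders = np.argsort(rng.random((self.variant_perm, n)), axis=1)
        pos_in_Yu = {w: i for i, w in enumerate(self._windows)}
        signals: list[RtQTLSignal] = []
        sig = np.asarray(sorted(sig_windows))
        for chunk, vsel in self._chunks(sig, size=32):
            if len(vsel) == 0:
                continue
            rows = np.array([pos_in_Yu[w] for w in chunk])
            Wc = self._Yu[rows]
            Gs = self._Gu[:, vsel]
            mask = self._cis_mask(chunk, vsel)
            obs_r = Wc @ Gs
            obs_p = corr_pvalues(obs_r, self._df)
            # permutation p-values per window: store |r| then convert lazily
            perm_abs = np.empty((len(chunk), self.variant_perm, len(vsel)), dtype=np.float32) \
                if len(chunk) * self.variant_perm * len(vsel) <= 40_000_000 else None
            if perm_abs is None:
                # fall back to per-window loop to bound memory
                for j, w in enumerate(chunk):
                    cis_cols = np.flatnonzero(mask[j])
                    if len(cis_cols) == 0:
                        continue
                    Gw = Gs[:, cis_cols]
                    Rn = np.abs(self._residualize_perms(Wc[j][orders]) @ Gw)
                    self._emit_signal(w, vsel[cis_cols], obs_r[j, cis_cols], obs_p[j, cis_cols], Rn, signals)
                continue
            for p0 in range(0, self.variant_perm, 64):
                block = orders[p0 : p0 + 64]
                P = Wc[:, block]  # (k, nb, n)
                k, nb = P.shape[0], P.shape[1]
                Pf = self._residualize_perms(P.reshape(k * nb, n))
                R = np.abs(Pf @ Gs).reshape(k, nb, -1)
                perm_abs[:, p0 : p0 + nb, :] = R.astype(np.float32)
            for j, w in enumerate(chunk):
                cis_cols = np.flatnonzero(mask[j])
                if len(cis_cols) == 0:
                    continue
                Rn = perm_abs[j][:, cis_cols].astype(np.float64)
                self._emit_signal(w, vsel[cis_cols], obs_r[j, cis_cols], obs_p[j, cis_cols], Rn, signals)
        return signals

    def _emit_signal(self, window, var_idx, r, p, null_abs_r, signals):
        perm_p = corr_pvalues(null_abs_r, self._df)
        pt = variant_threshold(p, perm_p, fdr=self.variant_fdr)
        if pt is None:
            return
        beta = r * self._y_sd[np.flatnonzero(self._windows == window)[0]] / np.where(
            self._g_sd[var_idx] == 0, 1.0, self._g_sd[var_idx]
        )
        t = r * np.sqrt(self._df / np.clip(1 - r**2, 1e-15, None))
        assoc = [
            AssociationResult(int(v), str(self.genotypes.ids[v]), int(window), float(b), float(ts), float(pv))
            for v, b, ts, pv in zip(var_idx, beta, t, p)
        ]
        signals.extend(
            define_signals(
                assoc, pt, self.genotypes,
                ld_r2=self.ld_r2, min_members=self.min_members, top_p_max=self.top_p_max,
            )
        )

    # -- public API --------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        scan_only: bool = False,
        apply_artifact_filter: bool | None = None,
        conditional: bool = True,
    ) -> "RtQTLResults":
        self._prepare()
        window_results = self._scan_windows(seed)
        sig_set = significant_windows(window_results, fdr=self.window_fdr)
        log.info("window scan: %d/%d windows significant at %.0f%% FDR",
                 len(sig_set), len(window_results), 100 * self.window_fdr)
        signals: list[RtQTLSignal] = []
        if not scan_only and sig_set:
            signals = self._variant_stage(sorted(sig_set), seed)
            signals = consolidate_signals(
                signals, self.smoothed, self.genotypes, ld_r2=self.ld_r2
            )
            if conditional:
                split = []
                for s in signals:
                    split.extend(conditional_split(s, self.smoothed, self.genotypes, self.covariates))
                signals = split
            for s in signals:
                associated_region(s, self.smoothed, self.genotypes, self.covariates)
            run_filter = apply_artifact_filter if apply_artifact_filter is not None else self.raw is not None
            if run_filter:
                if self.raw is None:
                    raise ValueError("artifact filters need the filtered raw matrix")
                for s in signals:
                    artifact_filter(s, self.raw, self.smoothed, self.genotypes, self.covariates)
            attach_variant_ids(signals, self.genotypes)
        return RtQTLResults(self, window_results, signals, seed=seed)


@dataclass
class RtQTLResults:
    """Fit output: window-level results, signals, diagnostics and plots."""

    model: RtQTLModel
    window_results: list[WindowResult]
    signals: list[RtQTLSignal]
    seed: int = 0
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def significant_window_ids(self) -> set[int]:
        return {w.window for w in self.window_results if w.significant}

    @property
    def signals_passing(self) -> list[RtQTLSignal]:
        return [s for s in self.signals if s.passes_filters]

    def windows_frame(self) -> pd.DataFrame:
        grid = self.model.smoothed.grid
        rows = [
            dict(
                window=w.window,
                chrom=grid.chrom[w.window],
                start=grid.start[w.window],
                end=grid.end[w.window],
                min_p_nominal=w.min_p_nominal,
                window_p=w.window_p,
                n_cis_variants=w.n_cis_variants,
                n_perm_used=w.n_perm_used,
                significant=w.significant,
            )
            for w in self.window_results
        ]
        return pd.DataFrame(rows)

    def signals_frame(self) -> pd.DataFrame:
        geno = self.model.genotypes
        rows = []
        for s in self.signals:
            rows.append(
                dict(
                    tag_id=s.tag_id,
                    chrom=s.chrom,
                    tag_pos=int(geno.pos[s.tag]),
                    top_p=s.top_p,
                    n_members=s.n_members,
                    threshold_pt=s.threshold_pt,
                    beta_tag=s.member_beta.get(s.tag, np.nan),
                    region_start=s.associated_region[0] if s.associated_region else np.nan,
                    region_end=s.associated_region[1] if s.associated_region else np.nan,
                    provenance=s.provenance,
                    passes_filters=s.passes_filters,
                )
            )
        return pd.DataFrame(rows)

    def inflation(self, n_windows: int = 200, seed: int | None = None) -> float:
        """Genomic-control lambda from variant chi-square statistics on a window sample
        (half drawn from putative rtQTL windows, half from the rest of the genome)."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        m = self.model
        tested = np.array([w.window for w in self.window_results])
        sig = np.array(sorted(self.significant_window_ids), dtype=int)
        other = tested[~np.isin(tested, sig)]
        take = []
        if len(sig):
            take.append(rng.choice(sig, size=min(n_windows // 2, len(sig)), replace=False))
        take.append(rng.choice(other, size=min(n_windows - len(take[0]) if take else n_windows, len(other)), replace=False))
        windows = np.concatenate(take)
        pos_in_Yu = {w: i for i, w in enumerate(m._windows)}
        chis = []
        for chunk, vsel in m._chunks(windows):
            if len(vsel) == 0:
                continue
            rows = np.array([pos_in_Yu[w] for w in chunk])
            r = m._Yu[rows] @ m._Gu[:, vsel]
            mask = m._cis_mask(chunk, vsel)
            p = corr_pvalues(r[mask], m._df)
            chis.append(stats.chi2.isf(p, df=1))
        return genomic_inflation(np.concatenate(chis))

    def summary(self) -> str:
        n_sig = len(self.significant_window_ids)
        lines = [
            "cis-rtQTL mapping results",
            "=" * 60,
            f"samples:              {self.model.smoothed.n_samples}",
            f"windows tested:       {len(self.window_results)}",
            f"significant windows:  {n_sig} (BH FDR {self.model.window_fdr:.2f})",
            f"variants after QC:    {self.model.genotypes.n_variants}",
            f"independent signals:  {len(self.signals)}",
            f"passing all filters:  {len(self.signals_passing)}",
        ]
        if self.signals:
            lines.append("-" * 60)
            lines.append(f"{'tag':>12} {'chrom':>6} {'pos':>10} {'top_p':>10} {'members':>8} {'region_kb':>10}")
            geno = self.model.genotypes
            for s in sorted(self.signals, key=lambda s: s.top_p)[:20]:
                span = (s.associated_region[1] - s.associated_region[0]) / 1e3 if s.associated_region else float("nan")
                lines.append(
                    f"{s.tag_id:>12} {s.chrom:>6} {int(geno.pos[s.tag]):>10d} "
                    f"{s.top_p:>10.2e} {s.n_members:>8d} {span:>10.0f}"
                )
        return "\n".join(lines)

    def plot_signal(self, signal: RtQTLSignal, ax=None):
        """Timing profiles around a signal, colored by tag genotype."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        m = self.model
        grid = m.smoothed.grid
        sl = grid.chrom_slice(signal.chrom)
        centers = grid.centers[sl] / 1e6
        dos = m.genotypes.dosages[:, signal.tag]
        colors = {0: "tab:blue", 1: "tab:gray", 2: "tab:red"}
        for s in range(m.smoothed.n_samples):
            ax.plot(centers, m.smoothed.values[s, sl], color=colors[int(dos[s])], lw=0.4, alpha=0.5)
        if signal.associated_region:
            ax.axvspan(signal.associated_region[0] / 1e6, signal.associated_region[1] / 1e6,
                       color="gold", alpha=0.2, label="associated region")
        ax.axvline(m.genotypes.pos[signal.tag] / 1e6, color="k", ls="--", lw=0.8, label="tag variant")
        ax.set_xlabel(f"{signal.chrom} (Mb)")
        ax.set_ylabel("timing (Z)")
        ax.legend(loc="best", fontsize=8)
        return ax


def select_phenotype_pcs(
    raw: RTMatrix,
    smoothed: RTMatrix,
    genotypes: GenotypeTable,
    k_range=range(0, 11),
    fdr: float = 0.10,
    seed: int = 0,
    perm_policy: PermutationPolicy | None = None,
    **model_kw,
) -> tuple[int, dict[int, int]]:
    """Pick the number of phenotype PCs maximizing significant-window count.

    Runs the window-level scan with a reduced permutation budget for each k;
    ties take the smallest k.
    """
    policy = perm_policy or PermutationPolicy(batches=(50, 100), min_exceedances=10)
    n = smoothed.n_samples
    counts: dict[int, int] = {}
    for k in k_range:
        if k + model_kw.get("n_genotype_pcs", 3) + 3 >= n:
            raise ValueError(f"k={k} leaves no residual degrees of freedom")
        model = RtQTLModel(
            smoothed, genotypes, raw=raw, n_phenotype_pcs=k,
            window_fdr=fdr, perm_policy=policy, **model_kw,
        )
        res = model.fit(seed=seed, scan_only=True)
        counts[k] = len(res.significant_window_ids)
    best = max(sorted(counts), key=lambda k: counts[k])
    return best, counts
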