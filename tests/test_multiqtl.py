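"""Multi-rtQTL grouping, additivity, interactions and spatial proximity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from replitime.genotypes import GenotypeTable
from replitime.mapping import RtQTLSignal
from replitime.multiqtl import (
    additive_vs_synergistic_lrt,
    early_allele_dosage,
    find_multi_regions,
    interaction_scan,
    pooled_additivity,
    prune_for_interaction,
    spatial_proximity_test,
)

from conftest import make_matrix


def _geno(dosages, positions, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=float)
    variants = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "id": [f"v{i}" for i in range(dosages.shape[1])], "ref": "A", "alt": "G",
    })
    return GenotypeTable(variants, dosages)


def _signal(tag, window, beta=0.5, top_p=1e-8, chrom="chr1"):
    return RtQTLSignal(
        tag=tag, tag_id=f"v{tag}", members=np.array([tag]),
        member_p={tag: top_p}, member_beta={tag: beta}, top_p=top_p,
        threshold_pt=1e-3, chrom=chrom, window=window, windows={window},
    )


def _additive_setup(seed=0, n=120, betas=(0.5, 0.4), noise=0.2, window_sep=20):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.4, size=(n, len(betas))).astype(float)
    y = g @ np.array(betas) + rng.normal(0, noise, n)
    w = 100
    vals = rng.normal(0, 0.1, (n, w))
    windows = [10 + i * window_sep for i in range(len(betas))]
    for j, wj in enumerate(windows):
        vals[:, wj] = y  # both signals' focal loci carry the shared phenotype
    sm = make_matrix(vals, state="raw")
    sm.state = "smoothed"
    geno = _geno(g, [wj * 10_000 + 5_000 for wj in windows])
    signals = [
        _signal(j, wj, beta=betas[j], top_p=1e-9 / (j + 1)) for j, wj in enumerate(windows)
    ]
    return geno, sm, signals, g, y


class TestFindMultiRegions:
    def test_single_signal_gives_no_region(self):
        geno, sm, signals, *_ = _additive_setup()
        assert find_multi_regions(signals[:1], sm, geno) == []

    def test_distant_loci_not_grouped(self):
        geno, sm, signals, g, y = _additive_setup(window_sep=85)  # 850 kb apart < 2 Mb
        # move the second signal's window out to 2.5 Mb: rebuild with wide matrix
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.1, (len(y), 400))
        vals[:, 10] = y
        vals[:, 310] = y  # 3 Mb away
        sm2 = make_matrix(vals, state="raw")
        sm2.state = "smoothed"
        s1 = _signal(0, 10)
        s2 = _signal(1, 310)
        assert find_multi_regions([s1, s2], sm2, geno) == []

    def test_planted_additive_signals_grouped_with_primary_first(self):
        geno, sm, signals, *_ = _additive_setup(betas=(0.6, 0.5, 0.4), seed=2)
        regions = find_multi_regions(signals, sm, geno)
        assert len(regions) == 1
        assert len(regions[0].signals) == 3
        assert regions[0].primary.top_p == min(s.top_p for s in signals)

    def test_member_without_added_power_pruned(self):
        geno, sm, signals, g, y = _additive_setup(betas=(0.6, 0.5))
        # a third signal whose tag duplicates the first (adds no explanatory power)
        dup = _geno(np.column_stack([g, g[:, 0]]), [105_000, 305_000, 505_000])
        s3 = _signal(2, 50, top_p=1e-4)
        sm.values[:, 50] = sm.values[:, 10]
        regions = find_multi_regions(signals + [s3], sm, dup)
        assert len(regions) == 1
        tags = {s.tag for s in regions[0].signals}
        assert len(tags) == 2 and 1 in tags  # exactly one of the duplicated tags survives
        assert len(tags & {0, 2}) == 1


class TestPooledAdditivity:
    def test_recovers_planted_slope_and_matches_ols(self):
        geno, sm, signals, g, y = _additive_setup(betas=(0.5, 0.5), noise=0.1, seed=4)
        regions = find_multi_regions(signals, sm, geno)
        slope, p = pooled_additivity(regions, sm, geno, standardize="none")
        assert p < 1e-6
        assert slope == pytest.approx(0.5, rel=0.15)
        # closed-form OLS identity on the pooled table
        reg = regions[0]
        yv = sm.values[:, reg.primary.window]
        x = np.sum([early_allele_dosage(s, geno) for s in reg.signals], axis=0)
        lr = stats.linregress(x, yv - yv.mean())
        assert slope == pytest.approx(lr.slope, rel=1e-9)

    def test_permuted_alleles_break_association(self):
        geno, sm, signals, g, y = _additive_setup(noise=0.3, seed=5)
        rng = np.random.default_rng(6)
        perm = _geno(g[rng.permutation(len(g))], list(geno.pos))
        regions = find_multi_regions(signals, sm, geno)
        _, p = pooled_additivity(regions, sm, perm, standardize="none")
        assert p > 0.05

    def test_single_allele_count_rejected(self):
        geno, sm, signals, *_ = _additive_setup()
        mono = _geno(np.ones((sm.n_samples, 2)), list(geno.pos))
        regions = find_multi_regions(signals, sm, geno)
        with pytest.raises(ValueError):
            pooled_additivity(regions, sm, mono, standardize="none")


class TestLRT:
    def test_chi2_df2_quantile(self):
        assert stats.chi2.sf(5.991, df=2) == pytest.approx(0.05, abs=1e-4)

    def test_requires_extreme_dosage_groups(self):
        y = np.random.default_rng(0).normal(size=20)
        dosage = np.repeat([1, 2, 3], [7, 7, 6])
        with pytest.raises(ValueError):
            additive_vs_synergistic_lrt(y, dosage)

    def test_lrt_never_negative(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            dosage = rng.integers(0, 5, size=30)
            if not ((dosage == 0).any() and (dosage == 4).any()):
                continue
            y = 0.3 * dosage + rng.normal(0, 0.5, 30)
            s, _ = additive_vs_synergistic_lrt(y, dosage)
            assert s >= -1e-9

    def test_matches_profile_likelihood_grid_oracle(self):
        """-2*logLR on a small toy equals an independent profile-likelihood search."""
        dosage = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        y = np.array([0.1, -0.2, 0.5, 0.4, 1.1, 0.9, 1.4, 1.6, 2.6, 2.9])
        stat, _ = additive_vs_synergistic_lrt(y, dosage)

        n = len(y)

        def rss_null():
            X = np.column_stack([np.ones(n), dosage.astype(float)])
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            return r @ r

        def rss_alt():
            # grid/optimizer over the free effective dosages d0, d4
            mid = (dosage >= 1) & (dosage <= 3)

            def rss_given(d0, d4):
                x = dosage.astype(float).copy()
                x[dosage == 0] = d0
                x[dosage == 4] = d4
                X = np.column_stack([np.ones(n), x])
                b, *_ = np.linalg.lstsq(X, y, rcond=None)
                r = y - X @ b
                return r @ r

            def inner(d0):
                return minimize_scalar(
                    lambda d4: rss_given(d0, d4), bounds=(1, 9), method="bounded",
                    options={"xatol": 1e-8},
                ).fun

            outer = minimize_scalar(inner, bounds=(-9, 3), method="bounded",
                                    options={"xatol": 1e-8})
            return outer.fun

        oracle = n * np.log(rss_null() / rss_alt())
        assert stat == pytest.approx(oracle, abs=1e-3)

    def test_additive_truth_p_uniform(self):
        from replitime.experiments import lrt_calibration

        r = lrt_calibration(seed=3, n_regions=300)
        assert r["ks_p"] > 0.01


class TestInteractionScan:
    def test_pure_additive_gives_null_interaction(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(200, 2)).astype(float)
        y = g[:, 0] + g[:, 1] + rng.normal(0, 1e-6, 200)
        geno = _geno(g, [10_000, 20_000])
        res = interaction_scan(y[None, :], geno, [(0, 0, 1)])
        assert abs(res[0]["interaction_beta"]) < 1e-4

    def test_planted_interaction_detected_with_minus_one_zero_one_coding(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(300, 2)).astype(float)
        y = (g[:, 0] - 1) * (g[:, 1] - 1) + rng.normal(0, 0.1, 300)
        geno = _geno(g, [10_000, 20_000])
        res = interaction_scan(y[None, :], geno, [(0, 0, 1)])
        assert res[0]["interaction_beta"] == pytest.approx(1.0, abs=0.05)
        assert res[0]["p"] < 1e-6
        # Bonferroni bookkeeping at 1000 hypothetical pairs would still pass
        assert res[0]["p"] * 1000 < 1e-3

    def test_collinear_pair_skipped(self):
        g = np.column_stack([np.repeat([0.0, 1, 2], 10)] * 2)
        geno = _geno(g, [10_000, 20_000])
        res = interaction_scan(np.zeros((1, 30)), geno, [(0, 0, 1)])
        assert res == []

    def test_pruning_reduces_windows_and_variants(self):
        rng = np.random.default_rng(2)
        vals = np.tile(rng.normal(size=(30, 1)), (1, 20)) + rng.normal(0, 0.01, (30, 20))
        sm = make_matrix(vals, state="raw")
        sm.state = "smoothed"
        g = np.tile(rng.binomial(2, 0.4, size=(30, 1)).astype(float), (1, 10))
        geno = _geno(g, list(np.arange(10) * 10_000))
        kept_w, kept_v = prune_for_interaction(sm, geno)
        assert len(kept_w) == 1 and len(kept_v) == 1


class TestSpatialProximity:
    def _pairs(self):
        return [("chr1", 2_500_000, "chr1", 5_000_000), ("chr1", 8_000_000, "chr1", 9_500_000)]

    def test_constant_matrix_gives_zero_z_and_half_p(self):
        m = np.ones((200, 200))
        out = spatial_proximity_test(self._pairs(), m, 100_000, {"chr1": 0}, n_perm=30, seed=0)
        assert out["z"] == 0.0 and out["p"] == 0.5

    def test_shift_magnitudes_within_one_to_two_megabases(self):
        m = np.random.default_rng(0).random((200, 200))
        out = spatial_proximity_test(self._pairs(), m, 100_000, {"chr1": 0}, n_perm=50, seed=1)
        assert (out["shifts"] >= 1_000_000).all() and (out["shifts"] <= 2_000_000).all()

    def test_planted_contact_enrichment_detected(self):
        rng = np.random.default_rng(2)
        m = rng.random((200, 200)) * 0.1
        for c1, p1, c2, p2 in self._pairs():
            m[p1 // 100_000, p2 // 100_000] = 1.0
        out = spatial_proximity_test(self._pairs(), m, 100_000, {"chr1": 0}, n_perm=100, seed=3)
        assert out["p"] < 0.05
        assert 0 <= out["shapiro_p"] <= 1

    def test_pair_outside_matrix_rejected(self):
        m = np.ones((10, 10))
        with pytest.raises(ValueError, match="outside"):
            spatial_proximity_test([("chr1", 5_000_000, "chr1", 100_000)], m, 100_000,
                                   {"chr1": 0}, n_perm=5, seed=0)
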