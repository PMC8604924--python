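"""cis-rtQTL mapping: association math, thresholds, signals and filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from replitime.genotypes import GenotypeTable, flip_alleles
from replitime.mapping import (
    AssociationResult,
    CovariateSet,
    PermutationPolicy,
    RtQTLSignal,
    consolidate_signals,
    define_signals,
    evaluate_artifact_criteria,
    extend_while_significant,
    genomic_inflation,
    merge_cohorts,
    significant_windows,
    validate_signals,
    validation_binomial_parameter,
    variant_threshold,
    window_scan,
    WindowResult,
)
from replitime.model import RtQTLModel

from conftest import make_matrix


def _toy_genotypes(rng, n_samples=100, n_variants=50, spacing=20_000, chrom="chr1"):
    dos = rng.binomial(2, 0.4, size=(n_samples, n_variants)).astype(float)
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n_variants,
            "pos": np.arange(n_variants) * spacing + spacing // 2,
            "id": [f"v{i}" for i in range(n_variants)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeTable(variants, dos)


class TestWindowScan:
    def test_single_variant_p_matches_closed_form_regression(self):
        """With no covariates, the variant p equals the textbook simple-regression t-test."""
        rng = np.random.default_rng(0)
        geno = _toy_genotypes(rng, n_samples=60, n_variants=1)
        y = 0.3 * geno.dosages[:, 0] + rng.normal(0, 1, 60)
        wr, assoc = window_scan(
            y, window=0, chrom="chr1", center=10_000.0, genotypes=geno,
            covariates=None, n_perm=50, seed=1,
        )
        lr = stats.linregress(geno.dosages[:, 0], y)
        assert assoc[0].p == pytest.approx(lr.pvalue, abs=1e-10)
        assert assoc[0].beta == pytest.approx(lr.slope, rel=1e-9)

    def test_variant_beyond_cis_radius_excluded(self):
        rng = np.random.default_rng(1)
        geno = _toy_genotypes(rng, n_samples=40, n_variants=2, spacing=1_200_000)
        # window centered at the first variant; second sits 1.2 Mb away
        _, assoc = window_scan(
            rng.normal(size=40), window=0, chrom="chr1",
            center=float(geno.pos[0]), genotypes=geno, covariates=None,
            n_perm=20, seed=1,
        )
        assert [a.variant for a in assoc] == [0]

    def test_no_cis_variants_skips_window(self):
        rng = np.random.default_rng(2)
        geno = _toy_genotypes(rng, n_samples=30, n_variants=1)
        wr, assoc = window_scan(
            rng.normal(size=30), window=0, chrom="chr9",
            center=10_000.0, genotypes=geno, covariates=None, n_perm=20, seed=1,
        )
        assert wr is None and assoc == []

    def test_null_window_p_uniform(self, small_cohort, profiled):
        """Window-level p-values on a cohort with no true associations are uniform."""
        _, sm = profiled
        rng = np.random.default_rng(3)
        geno = small_cohort.genotypes
        # destroy genotype-phenotype coupling by permuting samples in the phenotype
        perm = rng.permutation(sm.n_samples)
        model = RtQTLModel(
            sm.copy(values=sm.values[perm]), geno, n_phenotype_pcs=2,
            perm_policy=PermutationPolicy(batches=(100, 200), min_exceedances=25),
        )
        res = model.fit(seed=3, scan_only=True)
        wp = np.array([w.window_p for w in res.window_results])[::10]  # thin for independence
        assert stats.kstest(wp, "uniform").pvalue > 0.01


class TestSignificantWindows:
    def test_all_ones_gives_empty_set(self):
        wrs = [WindowResult(i, 1.0, 1.0, 5, 0) for i in range(10)]
        assert significant_windows(wrs) == set()

    def test_bh_closed_form_on_toy_list(self):
        p = [0.001] * 20 + [1.0] * 180
        wrs = [WindowResult(i, pv, pv, 5, 0) for i, pv in enumerate(p)]
        flagged = significant_windows(wrs, fdr=0.10)
        assert flagged == set(range(20))

    def test_stricter_fdr_flag_supported(self):
        p = [0.0004] * 1 + [0.03] * 4 + [1.0] * 95
        wrs = [WindowResult(i, pv, pv, 5, 0) for i, pv in enumerate(p)]
        at10 = significant_windows(wrs, fdr=0.10)
        at5 = significant_windows(wrs, fdr=0.05)
        assert at5 <= at10


class TestVariantThreshold:
    def test_fdr_formula_arithmetic(self):
        # 10 real p-values below the largest candidate; permutations average 1 passing
        real = np.linspace(1e-5, 1e-3, 10)
        perm = np.tile(np.concatenate([[5e-4], np.ones(9)]), (100, 1))
        pt = variant_threshold(real, perm, fdr=0.10)
        assert pt == pytest.approx(real.max())

    def test_zero_false_positives_gives_largest_observed_p(self):
        real = np.array([0.2, 0.5, 0.9])
        perm = np.ones((50, 3))
        assert variant_threshold(real, perm, fdr=0.10) == pytest.approx(0.9)

    def test_no_valid_threshold_returns_none(self):
        real = np.array([0.5])
        perm = np.full((50, 1), 1e-6)
        assert variant_threshold(real, perm, fdr=0.10) is None

    def test_matches_exhaustive_grid_oracle(self):
        rng = np.random.default_rng(7)
        real = rng.uniform(0, 1, 50)
        perm = rng.uniform(0, 1, (200, 50))
        got = variant_threshold(real, perm, fdr=0.10)
        # brute-force scan over every observed p as candidate threshold
        best = None
        for cand in sorted(real):
            fp = (perm <= cand).sum() / perm.shape[0]
            tp = (real <= cand).sum()
            if fp / tp <= 0.10:
                best = cand if best is None else max(best, cand)
        assert got == pytest.approx(best)


class TestDefineSignals:
    def _assoc(self, geno, pvals):
        return [
            AssociationResult(i, f"v{i}", 0, 0.1, 1.0, p) for i, p in enumerate(pvals)
        ]

    def test_all_in_ld_gives_one_signal(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.4, size=60).astype(float)
        dos = np.tile(base[:, None], (1, 12))
        variants = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(12) * 10_000, "id": [f"v{i}" for i in range(12)],
            "ref": "A", "alt": "G"})
        geno = GenotypeTable(variants, dos)
        sigs = define_signals(self._assoc(geno, np.full(12, 1e-5)), 1e-3, geno)
        assert len(sigs) == 1
        assert sigs[0].n_members == 12

    def test_nine_member_signal_dropped(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.4, size=60).astype(float)
        dos = np.tile(base[:, None], (1, 9))
        variants = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(9) * 10_000, "id": [f"v{i}" for i in range(9)],
            "ref": "A", "alt": "G"})
        geno = GenotypeTable(variants, dos)
        assert define_signals(self._assoc(geno, np.full(9, 1e-5)), 1e-3, geno) == []

    def test_two_ld_blocks_give_two_signals_with_correct_tags(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.4, size=80).astype(float)
        b = rng.binomial(2, 0.4, size=80).astype(float)
        dos = np.column_stack([np.tile(a[:, None], (1, 10)), np.tile(b[:, None], (1, 10))])
        variants = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(20) * 10_000, "id": [f"v{i}" for i in range(20)],
            "ref": "A", "alt": "G"})
        geno = GenotypeTable(variants, dos)
        pvals = np.concatenate([np.full(10, 1e-6), np.full(10, 1e-4)])
        pvals[3] = 1e-8   # block-A tag
        pvals[17] = 1e-5  # block-B tag
        sigs = define_signals(self._assoc(geno, pvals), 1e-3, geno)
        assert len(sigs) == 2
        assert {s.tag for s in sigs} == {3, 17}
        # every significant variant belongs to exactly one signal
        members = sorted(int(v) for s in sigs for v in s.members)
        assert members == list(range(20))


def _signal(tag, window, chrom="chr1", top_p=1e-6, members=None, geno=None, pt=1e-3, betas=None):
    members = np.asarray(members if members is not None else [tag])
    member_p = {int(v): top_p for v in members}
    member_beta = {int(v): (betas[int(v)] if betas else 0.5) for v in members}
    return RtQTLSignal(
        tag=tag, tag_id=f"v{tag}", members=members, member_p=member_p,
        member_beta=member_beta, top_p=top_p, threshold_pt=pt, chrom=chrom,
        window=window, windows={window},
    )


class TestConsolidation:
    def _setup(self, n=60, w=300, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.binomial(2, 0.4, size=n).astype(float)
        dos = np.column_stack([base] * 3 + [rng.binomial(2, 0.4, size=n).astype(float)])
        variants = pd.DataFrame({
            "chrom": "chr1", "pos": [10_000, 20_000, 2_600_000, 30_000],
            "id": [f"v{i}" for i in range(4)], "ref": "A", "alt": "G"})
        geno = GenotypeTable(variants, dos)
        vals = np.tile(base[:, None], (1, w)) + rng.normal(0, 0.3, (n, w))
        sm = make_matrix(vals, state="raw")
        sm.state = "smoothed"
        return geno, sm

    def test_same_variant_in_two_nearby_windows_consolidates(self):
        geno, sm = self._setup()
        s1 = _signal(0, 5, members=[0, 1])
        s2 = _signal(1, 55, members=[0, 1])  # 500 kb apart, same LD block
        merged = consolidate_signals([s1, s2], sm, geno, ld_r2=0.2)
        assert len(merged) == 1
        assert merged[0].windows == {5, 55}

    def test_windows_beyond_two_megabases_not_consolidated(self):
        geno, sm = self._setup()
        s1 = _signal(0, 5, members=[0, 1])
        s2 = _signal(1, 250, members=[0, 1])  # 2.45 Mb apart
        assert len(consolidate_signals([s1, s2], sm, geno)) == 2

    def test_uncorrelated_windows_not_consolidated(self):
        geno, sm = self._setup()
        rng = np.random.default_rng(9)
        sm.values[:, 60] = rng.normal(size=sm.n_samples)  # unrelated phenotype
        s1 = _signal(0, 5, members=[0, 1])
        s2 = _signal(1, 60, members=[0, 1])
        assert len(consolidate_signals([s1, s2], sm, geno)) == 2


class TestAssociatedRegionAndFilters:
    def test_extension_stops_at_first_nonsignificant_window(self):
        p = np.array([0.2, 0.01, 0.001, 0.03, 0.2])
        lo, hi = extend_while_significant(p, start=2, alpha=0.05)
        assert (lo, hi) == (1, 3)

    def test_single_significant_window_region(self):
        p = np.array([0.5, 0.6, 0.001, 0.7, 0.9])
        assert extend_while_significant(p, 2) == (2, 2)

    def test_artifact_criteria_instantiations(self):
        # raw support at only 4 windows -> fail criterion 1
        v = evaluate_artifact_criteria(
            raw_pvals=[0.01] * 4 + [0.5] * 6, smoothed_pvals=[0.005] * 10,
            removed_pvals=[], top_p=1e-4, n_region_windows=10,
        )
        assert not v["raw_support_5_windows"]
        # smoothed min 1e-6, raw min 1e-8: raw two orders lower -> fail criterion 2
        v = evaluate_artifact_criteria([1e-8] * 6, [1e-6] * 6, [], 1e-4, 6)
        assert not v["raw_vs_smoothed_order"]
        # raw min p 0.02 -> fail the final criterion
        v = evaluate_artifact_criteria([0.02] * 6, [0.001] * 6, [], 1e-4, 6)
        assert not v["raw_min_p_and_region_size"]

    def test_raw_vs_smoothed_order_rule_detail(self):
        """Raw more than one order of magnitude below smoothed fails criterion 2."""
        # raw HIGHER (less significant) than smoothed always passes
        v = evaluate_artifact_criteria([1e-4] * 6, [1e-6] * 6, [], 1e-4, 6)
        assert v["raw_vs_smoothed_order"]
        # raw within one order below smoothed passes
        v = evaluate_artifact_criteria([5e-7] * 6, [1e-6] * 6, [], 1e-4, 6)
        assert v["raw_vs_smoothed_order"]
        # raw three orders below smoothed fails
        v = evaluate_artifact_criteria([1e-9] * 6, [1e-6] * 6, [], 1e-4, 6)
        assert not v["raw_vs_smoothed_order"]

    def test_removed_data_relaxation_by_top_p(self):
        # removed min 1.5 orders below raw: fails at top_p 1e-4 (1-order rule),
        # passes at top_p 1e-6 (relaxed to 2 orders)
        raw = [1e-3] * 6
        removed = [10 ** (-4.5)] * 2
        assert not evaluate_artifact_criteria(raw, raw, removed, 1e-4, 6)["removed_vs_raw_order"]
        assert evaluate_artifact_criteria(raw, raw, removed, 1e-6, 6)["removed_vs_raw_order"]
        # 2.5 orders below needs the 4-order relaxation (top_p <= 5e-8)
        removed25 = [10 ** (-5.5)] * 2
        assert not evaluate_artifact_criteria(raw, raw, removed25, 1e-6, 6)["removed_vs_raw_order"]
        assert evaluate_artifact_criteria(raw, raw, removed25, 1e-9, 6)["removed_vs_raw_order"]
        # count rule: 3 removed windows beating raw fails unless top_p <= 5e-8
        removed3 = [1e-5] * 3
        assert not evaluate_artifact_criteria(raw, raw, removed3, 1e-6, 6)["removed_windows_beating_raw"]
        assert evaluate_artifact_criteria(raw, raw, removed3, 1e-9, 6)["removed_windows_beating_raw"]


class TestInflation:
    def test_analytic_median_gives_lambda_one(self):
        m = stats.chi2.ppf(0.5, 1)
        assert genomic_inflation(np.full(200, m)) == pytest.approx(1.0)

    def test_scaling_and_null(self):
        rng = np.random.default_rng(0)
        draws = rng.chisquare(1, size=100_000)
        assert genomic_inflation(draws) == pytest.approx(1.0, abs=0.02)
        assert genomic_inflation(2 * draws) == pytest.approx(2.0, abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))


class TestMergeCohorts:
    def _mk(self, tag_id, beta, top_p, member_p=None):
        s = _signal(0, 0, top_p=top_p, members=[0])
        s.member_beta = {0: beta}
        s.member_p = {0: member_p if member_p is not None else top_p}
        s.member_ids = {0: tag_id}
        return s

    def test_identical_signal_counted_once(self):
        a = self._mk("rs1", 0.5, 1e-6)
        b = self._mk("rs1", 0.4, 1e-6)
        assert len(merge_cohorts([a], [b])) == 1

    def test_opposite_effect_sign_keeps_both(self):
        a = self._mk("rs1", 0.5, 1e-6)
        b = self._mk("rs1", -0.4, 1e-6)
        assert len(merge_cohorts([a], [b])) == 2

    def test_shared_variant_three_orders_above_top_p_keeps_both(self):
        a = self._mk("rs1", 0.5, 1e-6)
        b = self._mk("rs1", 0.4, top_p=1e-6, member_p=1e-3)  # 3 orders above B's top p
        assert len(merge_cohorts([a], [b])) == 2


class TestValidation:
    def test_binomial_parameter_value(self):
        assert validation_binomial_parameter(4, 0.05) == pytest.approx(0.0963, abs=5e-5)

    def test_zero_datasets_rejected(self):
        with pytest.raises(ValueError):
            validation_binomial_parameter(0)

    def test_cohort_binomial_p_matches_exact_oracle(self):
        # 300 signals, 200 validated under parameter 0.0963
        param = validation_binomial_parameter(4)
        p = stats.binomtest(200, 300, param, alternative="greater").pvalue
        oracle = sum(
            stats.binom.pmf(k, 300, param) for k in range(200, 301)
        )
        assert p == pytest.approx(oracle, rel=1e-9)


class TestReferenceAlleleSymmetry:
    def test_flipping_coding_flips_beta_and_preserves_p(self):
        rng = np.random.default_rng(11)
        geno = _toy_genotypes(rng, n_samples=80, n_variants=5)
        y = 0.4 * geno.dosages[:, 2] + rng.normal(0, 1, 80)
        _, assoc = window_scan(y, 0, "chr1", float(geno.pos[2]), geno, None, n_perm=20, seed=1)
        flipped = flip_alleles(geno, np.array([2]))
        _, assoc_f = window_scan(y, 0, "chr1", float(geno.pos[2]), flipped, None, n_perm=20, seed=1)
        a = {x.variant: x for x in assoc}
        b = {x.variant: x for x in assoc_f}
        assert b[2].beta == pytest.approx(-a[2].beta, rel=1e-9)
        assert b[2].p == pytest.approx(a[2].p, abs=1e-12)


class TestPhenotypePCSelection:
    def test_null_cohort_ties_take_smallest_k(self, small_cohort, profiled):
        from replitime.model import select_phenotype_pcs

        fr, sm = profiled
        rng = np.random.default_rng(21)
        perm = rng.permutation(sm.n_samples)
        null_sm = sm.copy(values=sm.values[perm])
        null_fr = fr.copy(values=fr.values[perm])
        best, counts = select_phenotype_pcs(
            null_fr, null_sm, small_cohort.genotypes, k_range=range(0, 3), seed=2,
        )
        assert best == min(k for k, c in counts.items() if c == max(counts.values()))
        assert max(counts.values()) <= 3  # essentially nothing on a null cohort
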