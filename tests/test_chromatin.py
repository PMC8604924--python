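"""Matched controls, enrichment, combination search, me3-ac-hyper regions,
allelic covariation, and TF motif association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from replitime.chromatin import (
    allelic_covariation,
    build_matched_controls,
    build_me3achyper,
    combination_search,
    feature_enrichment,
    five_mark_sites,
    tf_motif_association,
)
from replitime.genotypes import GenotypeTable
from replitime.grid import Intervals
from replitime.mapping import RtQTLSignal
from replitime.tracks import IntervalTrackSet

from conftest import make_matrix


def _geno(rng, n_samples=30, n_variants=400, spacing=10_000):
    dos = rng.binomial(2, rng.uniform(0.2, 0.5, n_variants), size=(n_samples, n_variants)).astype(float)
    variants = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(n_variants) * spacing + spacing // 2,
        "id": [f"v{i}" for i in range(n_variants)], "ref": "A", "alt": "G",
    })
    return GenotypeTable(variants, dos)


def _signal(tag, members, geno, beta=0.5, window=0):
    members = np.asarray(members)
    return RtQTLSignal(
        tag=int(tag), tag_id=str(geno.ids[tag]), members=members,
        member_p={int(v): 1e-6 for v in members},
        member_beta={int(v): beta for v in members},
        top_p=1e-6, threshold_pt=1e-3, chrom="chr1", window=window, windows={window},
    )


@pytest.fixture()
def control_setup():
    rng = np.random.default_rng(0)
    geno = _geno(rng)
    sm = make_matrix(rng.normal(0, 0.2, (geno.n_samples, geno.n_variants)), state="raw")
    sm.state = "smoothed"
    peaks = [("chr1", p) for p in range(200_000, 4_000_000, 400_000)]
    valleys = [("chr1", p) for p in range(400_000, 4_000_000, 400_000)]
    signals = [_signal(50, [48, 49, 50, 51, 52], geno)]
    return rng, geno, sm, peaks, valleys, signals


class TestMatchedControls:
    def test_matching_invariants_hold(self, control_setup):
        rng, geno, sm, peaks, valleys, signals = control_setup
        controls = build_matched_controls(signals, geno, peaks, valleys, sm, min_matches=5)
        tag = signals[0].tag
        from replitime.chromatin import variant_annotations

        ann = variant_annotations(geno, peaks, valleys, sm)
        for cand in controls.matched_tags[0]:
            assert abs(geno.pos[cand] - geno.pos[tag]) >= 2_000_000 or geno.chrom[cand] != geno.chrom[tag]
            assert abs(ann["maf"][cand] - ann["maf"][tag]) < 0.05
            assert abs(ann["peak_dist"][cand] - ann["peak_dist"][tag]) < 50_000
            assert abs(ann["valley_dist"][cand] - ann["valley_dist"][tag]) < 50_000
            assert abs(ann["timing"][cand] - ann["timing"][tag]) < 0.5
        # the real tag itself can never be its own match (distance 0)
        assert tag not in controls.matched_tags[0]

    def test_too_few_matches_flags_exclusion(self, control_setup):
        rng, geno, sm, peaks, valleys, signals = control_setup
        controls = build_matched_controls(signals, geno, peaks, valleys, sm, min_matches=10_000)
        assert 0 in controls.excluded
        assert controls.usable == []

    def test_drawn_control_sets_match_cardinality(self, control_setup):
        rng, geno, sm, peaks, valleys, signals = control_setup
        controls = build_matched_controls(signals, geno, peaks, valleys, sm, min_matches=1)
        drawn = controls.draw(0, np.random.default_rng(1))
        assert len(drawn) <= signals[0].n_members
        assert len(drawn) >= 1


class TestFeatureEnrichment:
    def test_genome_wide_feature_gives_unit_fold(self, control_setup):
        rng, geno, sm, peaks, valleys, signals = control_setup
        controls = build_matched_controls(signals, geno, peaks, valleys, sm, min_matches=1)
        feature = Intervals.from_records([("chr1", 0, 10_000_000)])
        res = feature_enrichment(signals, feature, controls, geno, n_perm=20, seed=1)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_extreme_planted_enrichment(self):
        rng = np.random.default_rng(2)
        geno = _geno(rng, n_samples=30, n_variants=3000, spacing=10_000)
        sm = make_matrix(np.zeros((30, 3000)), state="raw")
        sm.state = "smoothed"
        peaks = [("chr1", p) for p in range(1_000_000, 30_000_000, 2_000_000)]
        valleys = [("chr1", p) for p in range(2_000_000, 30_000_000, 2_000_000)]
        tags = list(range(100, 3000, 55))[:50]
        signals = [_signal(t, [t], geno) for t in tags]
        feature = Intervals.from_records(
            [("chr1", int(geno.pos[t]) - 100, int(geno.pos[t]) + 100) for t in tags]
        )
        controls = build_matched_controls(signals, geno, peaks, valleys, sm, min_matches=1)
        res = feature_enrichment(signals, feature, controls, geno, n_perm=30, seed=2)
        assert res.n_overlapping == len(controls.usable)
        assert res.p < 1e-10

    def test_p_matches_exact_binomial_oracle(self, control_setup):
        rng, geno, sm, peaks, valleys, signals = control_setup
        controls = build_matched_controls(signals, geno, peaks, valleys, sm, min_matches=1)
        feature = Intervals.from_records([("chr1", 480_000, 530_000)])
        res = feature_enrichment(signals, feature, controls, geno, n_perm=25, seed=3)
        alt = "greater" if res.fold >= 1 else "less"
        oracle = stats.binomtest(
            res.n_overlapping, res.n_total, res.expected_fraction, alternative=alt
        ).pvalue
        assert res.p == pytest.approx(oracle, rel=1e-12)

    def test_empty_feature_rejected(self, control_setup):
        rng, geno, sm, peaks, valleys, signals = control_setup
        controls = build_matched_controls(signals, geno, peaks, valleys, sm, min_matches=1)
        with pytest.raises(ValueError):
            feature_enrichment(signals, Intervals(), controls, geno)


class TestCombinationSearch:
    def _sets(self, rng, n_snps=300, n_ctrl=3000):
        snp_pos = np.arange(n_snps) * 10_000 + 5_000
        ctrl_pos = np.arange(n_ctrl) * 10_000 + 50_000_000
        return snp_pos, ctrl_pos

    def _features(self, rng, snp_pos, ctrl_pos, planted, others, snp_frac=0.4, bg_frac=0.02):
        feats = {}
        carriers = rng.random(len(snp_pos)) < snp_frac
        for name in planted:
            recs = [("chr1", int(p) - 50, int(p) + 50) for p in snp_pos[carriers]]
            recs += [("chr1", int(p) - 50, int(p) + 50)
                     for p in ctrl_pos[rng.random(len(ctrl_pos)) < bg_frac]]
            feats[name] = Intervals.from_records(recs)
        for name in others:
            hit_s = rng.random(len(snp_pos)) < bg_frac
            hit_c = rng.random(len(ctrl_pos)) < bg_frac
            recs = [("chr1", int(p) - 50, int(p) + 50) for p in snp_pos[hit_s]]
            recs += [("chr1", int(p) - 50, int(p) + 50) for p in ctrl_pos[hit_c]]
            feats[name] = Intervals.from_records(recs) if recs else Intervals.from_records(
                [("chr1", 0, 1)])
        return feats

    def test_single_enriched_feature_stops_after_level_one(self):
        rng = np.random.default_rng(4)
        snp_pos, ctrl_pos = self._sets(rng)
        feats = self._features(rng, snp_pos, ctrl_pos, ["A"], ["B", "C", "D"])
        out = combination_search(
            feats, ["chr1"] * len(snp_pos), snp_pos, ["chr1"] * len(ctrl_pos), ctrl_pos
        )
        assert [sorted(r.combination) for r in out[1]] == [["A"]]
        assert 2 not in out

    def test_co_planted_trio_found_with_sound_parent_chain(self):
        rng = np.random.default_rng(5)
        snp_pos, ctrl_pos = self._sets(rng)
        feats = self._features(rng, snp_pos, ctrl_pos, ["A", "B", "C"], ["D", "E", "F"])
        out = combination_search(
            feats, ["chr1"] * len(snp_pos), snp_pos, ["chr1"] * len(ctrl_pos), ctrl_pos
        )
        level3 = {tuple(sorted(r.combination)) for r in out.get(3, [])}
        assert ("A", "B", "C") in level3
        # soundness: every reported combination extends an enriched parent
        for level, results in out.items():
            if level == 1:
                continue
            prev = {r.combination for r in out[level - 1]}
            for r in results:
                assert r.parent in prev
        assert 4 not in out

    def test_termination_when_nothing_passes(self):
        rng = np.random.default_rng(6)
        snp_pos, ctrl_pos = self._sets(rng, n_snps=100, n_ctrl=1000)
        feats = self._features(rng, snp_pos, ctrl_pos, [], ["A", "B", "C"])
        out = combination_search(
            feats, ["chr1"] * len(snp_pos), snp_pos, ["chr1"] * len(ctrl_pos), ctrl_pos
        )
        assert out.get(1, []) == [] or all(r.odds_ratio <= 1 for r in out[1])


class TestMe3AcHyper:
    def _ac_tracks(self, n, start=0, end=100_000):
        return {f"ac{i}": Intervals.from_records([("chr1", start, end)]) for i in range(n)}

    def test_five_mark_sites_are_mutual_overlaps(self):
        tracks = {
            "a": Intervals.from_records([("chr1", 0, 100)]),
            "b": Intervals.from_records([("chr1", 50, 150)]),
            "c": Intervals.from_records([("chr1", 80, 200)]),
        }
        sites = five_mark_sites(tracks, ("a", "b", "c"))
        assert [(r.start, r.end) for r in sites.df.itertuples()] == [(80, 100)]

    def test_sites_below_eleven_acetylations_excluded(self):
        sites = Intervals.from_records([("chr1", 10_000, 12_000)])
        assert build_me3achyper(sites, self._ac_tracks(10)) == []
        regions = build_me3achyper(sites, self._ac_tracks(11))
        assert len(regions) == 1
        assert regions[0].acetylation_count == 11

    def test_nearby_regions_merged_within_ten_kilobases(self):
        sites = Intervals.from_records([("chr1", 10_000, 12_000), ("chr1", 20_000, 22_000)])
        regions = build_me3achyper(sites, self._ac_tracks(12))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (10_000, 22_000)

    def test_distant_regions_not_merged(self):
        sites = Intervals.from_records([("chr1", 10_000, 12_000), ("chr1", 40_000, 42_000)])
        regions = build_me3achyper(sites, self._ac_tracks(12))
        assert len(regions) == 2

    def test_no_sites_gives_empty_list(self):
        assert build_me3achyper(Intervals(), self._ac_tracks(12)) == []


class TestAllelicCovariation:
    def _tracks_with_coupling(self, rng, geno, snps, p_early, p_late, mark="m"):
        tracks = IntervalTrackSet()
        for s in range(geno.n_samples):
            recs = []
            for v in snps:
                g = geno.dosages[s, v]
                p = p_early if g == 2 else (p_late if g == 0 else 0.5 * (p_early + p_late))
                if rng.random() < p:
                    pos = int(geno.pos[v])
                    recs.append(("chr1", pos - 500, pos + 500))
            tracks.add(mark, Intervals.from_records(recs) if recs else Intervals(),
                       sample=f"S{s:04d}")
        return tracks

    def test_parameter_formula_instantiation(self):
        """p_late=0.2 with a unit permutation ratio gives binomial parameter 0.2."""
        rng = np.random.default_rng(7)
        geno = _geno(rng, n_samples=20, n_variants=200)
        snps = np.arange(0, 200, 5)
        tracks = self._tracks_with_coupling(rng, geno, snps, p_early=0.2, p_late=0.2)
        res = allelic_covariation(
            snps, np.ones(len(snps), dtype=int), geno, tracks, ["m"],
            control_snps=snps, n_perm=10, seed=1,
        )[0]
        # the controls are the sites themselves at equal presence rates: ratio ~ 1
        assert res.binomial_parameter == pytest.approx(res.p_late * np.clip(
            res.p_perm_early / res.p_perm_late, 0.01, 100), rel=1e-9)
        assert res.p > 0.01

    def test_mark_everywhere_gives_p_one(self):
        rng = np.random.default_rng(8)
        geno = _geno(rng, n_samples=10, n_variants=50)
        tracks = IntervalTrackSet()
        full = Intervals.from_records([("chr1", 0, 10_000_000)])
        for s in range(10):
            tracks.add("m", full, sample=f"S{s:04d}")
        snps = np.arange(0, 50, 2)
        res = allelic_covariation(snps, np.ones(len(snps), dtype=int), geno, tracks,
                                  ["m"], control_snps=snps, n_perm=5, seed=2)[0]
        assert res.p_early_observed == 1.0 and res.p_late == 1.0
        assert res.p == pytest.approx(1.0)

    def test_planted_coupling_significant_and_matches_binomial_oracle(self):
        rng = np.random.default_rng(9)
        geno = _geno(rng, n_samples=14, n_variants=400)
        snps = np.arange(0, 400, 4)
        tracks = self._tracks_with_coupling(rng, geno, snps, p_early=0.8, p_late=0.2)
        far = np.arange(1, 400, 4)  # uncoupled control SNPs
        res = allelic_covariation(snps, np.ones(len(snps), dtype=int), geno, tracks,
                                  ["m"] * 1 + [("m",)] * 0, control_snps=far,
                                  n_perm=10, seed=3)[0]
        oracle = stats.binomtest(res.k_early_present, res.n_early_pairs,
                                 res.binomial_parameter, alternative="two-sided").pvalue
        assert res.p == pytest.approx(oracle, rel=1e-12)
        assert res.p * 29 < 0.05  # survives Bonferroni over a 29-mark panel
        assert res.log_ratio > 0

    def test_no_polymorphic_sites_rejected(self):
        rng = np.random.default_rng(10)
        geno = _geno(rng, n_samples=6, n_variants=10)
        geno.dosages[:] = 1.0
        tracks = IntervalTrackSet()
        for s in range(6):
            tracks.add("m", Intervals(), sample=f"S{s:04d}")
        with pytest.raises(ValueError):
            allelic_covariation(np.arange(10), np.ones(10, dtype=int), geno, tracks,
                                ["m"], control_snps=np.arange(10), n_perm=2, seed=0)


class TestTFMotifAssociation:
    def _setup(self, rng, n_signals=20):
        geno = _geno(rng, n_samples=30, n_variants=3000)
        sm = make_matrix(np.zeros((30, 3000)), state="raw")
        sm.state = "smoothed"
        peaks = [("chr1", p) for p in range(1_000_000, 30_000_000, 2_000_000)]
        valleys = [("chr1", p) for p in range(2_000_000, 30_000_000, 2_000_000)]
        tags = list(range(100, 3000, 100))[:n_signals]
        signals = [_signal(t, [t], geno, beta=0.5) for t in tags]
        controls = build_matched_controls(signals, geno, peaks, valleys, sm, min_matches=1)
        return geno, signals, controls, tags

    def test_weighting_rule_and_chi2_oracle(self):
        rng = np.random.default_rng(11)
        geno, signals, controls, tags = self._setup(rng)
        rows = []
        for t in tags:
            # alt (early) allele scores higher by 2.0 for TF1
            rows.append(dict(variant_id=str(geno.ids[t]), tf="TF1", score_ref=1.0, score_alt=3.0))
        for v in range(0, 3000, 3):
            rows.append(dict(variant_id=str(geno.ids[v]), tf="TF1",
                             score_ref=2.0, score_alt=2.0 + rng.normal(0, 0.5)))
        table = pd.DataFrame(rows).drop_duplicates("variant_id")
        table["tf"] = "TF1"
        res = tf_motif_association(signals, table, geno, controls, n_perm=10,
                                   min_overlap=5, seed=4)
        assert len(res) == 1
        r = res[0]
        assert r.early_weight == pytest.approx(2.0 * len(signals))
        assert r.late_weight == 0.0
        # chi-squared statistic equals the closed-form 2x2 computation
        obs = np.array([[r.early_weight, r.late_weight],
                        [r.perm_early_weight, r.perm_late_weight]])
        chi2, p = stats.chi2_contingency(obs, correction=False)[:2]
        assert r.chi2 == pytest.approx(chi2, rel=1e-12)
        assert r.p == pytest.approx(p, rel=1e-12)

    def test_zero_score_differences_contribute_nothing(self):
        rng = np.random.default_rng(12)
        geno, signals, controls, tags = self._setup(rng)
        rows = [dict(variant_id=str(geno.ids[v]), tf="TF1", score_ref=1.0, score_alt=1.0)
                for v in range(0, 3000, 2)]
        res = tf_motif_association(signals, pd.DataFrame(rows), geno, controls,
                                   n_perm=5, min_overlap=5, seed=5)
        assert res[0].early_weight == 0.0 and res[0].late_weight == 0.0
        assert res[0].p == pytest.approx(1.0)

    def test_sparse_tf_excluded_by_overlap_rule(self):
        rng = np.random.default_rng(13)
        geno, signals, controls, tags = self._setup(rng)
        rows = [dict(variant_id=str(geno.ids[tags[0]]), tf="TF1", score_ref=1.0, score_alt=2.0)]
        res = tf_motif_association(signals, pd.DataFrame(rows), geno, controls,
                                   n_perm=5, min_overlap=15, seed=6)
        assert res == []
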