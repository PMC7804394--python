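"""Consensus THS construction, matrix filtering, and TSS geometry."""

import numpy as np
import pandas as pd
import pytest

from accessmarks import consensus as cons
from accessmarks.intervals import GenomicInterval, PeakSet, intersect, merge
from accessmarks.io import GeneModel, SignalTrack
from accessmarks.simulate import SimSpec, simulate_genome, simulate_ths, simulate_ths_replicates

from _oracles import intervals_from_mask, mask_of

GI = GenomicInterval


def track_from(records):
    return SignalTrack.from_records(records)


class TestReplicateConsensus:
    def test_intersect_mode_is_basepair_intersection(self):
        r1 = PeakSet("a_rep1", [GI("chr1", 0, 100), GI("chr1", 500, 600)])
        r2 = PeakSet("a_rep2", [GI("chr1", 50, 150), GI("chr1", 700, 800)])
        got = cons.replicate_consensus(r1, r2)
        assert got.intervals == [GI("chr1", 50, 100)]

    def test_union_mode_keeps_reproducible_peaks_whole(self):
        r1 = PeakSet("a_rep1", [GI("chr1", 0, 100), GI("chr1", 500, 600)])
        r2 = PeakSet("a_rep2", [GI("chr1", 50, 150), GI("chr1", 700, 800)])
        got = cons.replicate_consensus(r1, r2, mode="union")
        assert got.intervals == [GI("chr1", 0, 150)]

    def test_unknown_mode_rejected(self):
        r = PeakSet("x", [GI("chr1", 0, 10)])
        with pytest.raises(ValueError, match="mode"):
            cons.replicate_consensus(r, r, mode="nope")

    def test_matches_mask_oracle_on_simulated_replicates(self, toy_genome, rng):
        spec = SimSpec(chrom_sizes={"chr1": 1_000_000}, n_ths=30,
                       genotypes=("WT",), accessibility_multipliers={"WT": 1.0})
        g = simulate_genome(spec)
        _, reps = simulate_ths_replicates(spec, g, seed=2)
        r1, r2 = reps["WT"]
        got = cons.replicate_consensus(r1, r2)
        m1 = mask_of(r1.intervals, g)
        m2 = mask_of(r2.intervals, g)
        expect = intervals_from_mask({c: m1[c] & m2[c] for c in g})
        assert got.intervals == expect


class TestBuildConsensus:
    def test_union_across_genotypes_with_provenance(self):
        wt = PeakSet("WT", [GI("chr1", 0, 100)])
        mut = PeakSet("m", [GI("chr1", 50, 150), GI("chr2", 0, 60)])
        regions = cons.build_consensus({"WT": wt, "m": mut})
        assert [(c.interval.chrom, c.interval.start, c.interval.end) for c in regions] == [
            ("chr1", 0, 150), ("chr2", 0, 60)
        ]
        assert regions[0].provenance == ("WT", "m")
        assert regions[1].provenance == ("m",)
        assert regions[0].region_id == "chr1:0-150"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cons.build_consensus({})


class TestQPass:
    def test_requires_both_replicates_below_cutoff(self):
        regions = cons.build_consensus({"WT": PeakSet("WT", [GI("chr1", 0, 100)])})
        good = GI("chr1", 10, 60, qvalue=0.01)
        bad = GI("chr1", 10, 60, qvalue=0.2)
        noq = GI("chr1", 10, 60)
        both = cons.genotype_qpass(regions, {"WT": [PeakSet("r1", [good]), PeakSet("r2", [good])]})
        one = cons.genotype_qpass(regions, {"WT": [PeakSet("r1", [good]), PeakSet("r2", [bad])]})
        none = cons.genotype_qpass(regions, {"WT": [PeakSet("r1", [noq]), PeakSet("r2", [noq])]})
        assert bool(both.iloc[0, 0]) is True
        assert bool(one.iloc[0, 0]) is False
        assert bool(none.iloc[0, 0]) is False

    def test_cutoff_is_strict(self):
        regions = cons.build_consensus({"WT": PeakSet("WT", [GI("chr1", 0, 100)])})
        at_cut = GI("chr1", 10, 60, qvalue=0.05)
        flags = cons.genotype_qpass(
            regions, {"WT": [PeakSet("r1", [at_cut]), PeakSet("r2", [at_cut])]}
        )
        assert bool(flags.iloc[0, 0]) is False


class TestMatrix:
    def test_length_weighted_means(self):
        regions = cons.build_consensus({"WT": PeakSet("WT", [GI("chr1", 0, 100)])})
        track = track_from([("chr1", 0, 50, 2.0), ("chr1", 50, 100, 4.0)])
        m = cons.build_matrix(regions, {"WT_rep1": track})
        assert m.loc["chr1:0-100", "WT_rep1"] == pytest.approx(3.0)

    def test_filter_threshold_is_pooled_percentile(self, rng):
        vals = rng.uniform(0, 20, size=(400, 4))
        m = pd.DataFrame(vals, index=[f"r{i}" for i in range(400)],
                         columns=["a", "b", "c", "d"])
        kept, thr = cons.filter_matrix(m, percentile=5.0)
        assert thr == pytest.approx(np.percentile(vals.ravel(), 5.0))
        assert ((m.max(axis=1) >= thr) == m.index.isin(kept.index)).all()

    def test_fixed_floor_mode(self):
        m = pd.DataFrame({"a": [1.0, 5.0]}, index=["low", "high"])
        kept, thr = cons.filter_matrix(m, percentile=None, fallback_min=3.0)
        assert thr == 3.0 and list(kept.index) == ["high"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cons.filter_matrix(pd.DataFrame())


class TestConfidenceFilter:
    def test_needs_cpm_and_qpass(self):
        regions = cons.build_consensus({
            "WT": PeakSet("WT", [GI("chr1", 0, 100), GI("chr1", 500, 600),
                                 GI("chr1", 900, 1000)])
        })
        rids = [c.region_id for c in regions]
        matrix = pd.DataFrame(
            {"WT_rep1": [10.0, 1.0, 10.0], "WT_rep2": [10.0, 1.0, 10.0]}, index=rids
        )
        qpass = pd.DataFrame({"WT": [True, True, False]}, index=rids)
        kept = cons.confidence_filter(regions, matrix, qpass,
                                      {"WT_rep1": "WT", "WT_rep2": "WT"}, min_cpm=3.0)
        assert [c.region_id for c in kept] == [rids[0]]

    def test_cpm_is_genotype_mean_not_per_replicate(self):
        regions = cons.build_consensus({"WT": PeakSet("WT", [GI("chr1", 0, 100)])})
        rid = regions[0].region_id
        # one strong and one weak replicate: mean 3.5 > 3 keeps the region
        matrix = pd.DataFrame({"WT_rep1": [6.0], "WT_rep2": [1.0]}, index=[rid])
        qpass = pd.DataFrame({"WT": [True]}, index=[rid])
        kept = cons.confidence_filter(regions, matrix, qpass,
                                      {"WT_rep1": "WT", "WT_rep2": "WT"}, min_cpm=3.0)
        assert len(kept) == 1


class TestDifferentialAccessibility:
    def test_doubling_without_pseudocount_bias(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(2.5, 0.3, 300)
        m = pd.DataFrame({
            "WT_rep1": base, "WT_rep2": base,
            "mut_rep1": 2 * base, "mut_rep2": 2 * base,
        }, index=[f"r{i}" for i in range(300)])
        df = cons.differential_accessibility(
            m, {c: c.split("_")[0] for c in m.columns}, "mut"
        )
        # pseudocount 0.5 shrinks log2FC slightly below 1 but never above
        assert ((df["log2fc"] > 0.9) & (df["log2fc"] <= 1.0)).all()
        assert (df["direction"] == "increased").all()

    def test_unchanged_when_groups_identical(self):
        m = pd.DataFrame({
            "WT_rep1": [5.0, 8.0], "WT_rep2": [5.0, 8.0],
            "mut_rep1": [5.0, 8.0], "mut_rep2": [5.0, 8.0],
        }, index=["a", "b"])
        df = cons.differential_accessibility(
            m, {c: c.split("_")[0] for c in m.columns}, "mut"
        )
        assert (df["direction"] == "unchanged").all()
        assert (df["p"] == 1.0).all()


class TestTSSGeometry:
    def make_regions(self, positions, width=10):
        return cons.build_consensus({
            "WT": PeakSet("WT", [GI("chr1", p - width // 2, p + width // 2) for p in positions])
        })

    def test_bins_by_signed_distance(self):
        genes = [GeneModel("g", "chr1", 10_000, 12_000, "+")]
        # centers: in body; 500 upstream; 2000 upstream; 5000 upstream; downstream
        regions = self.make_regions([11_000, 9_500, 8_000, 5_000, 13_000])
        df = cons.tss_distribution(regions, genes)
        assert df.loc["gene_body", "count"] == 1
        assert df.loc["upstream_0_1000", "count"] == 1
        assert df.loc["upstream_1000_3000", "count"] == 1
        assert df.loc["upstream_gt_3000", "count"] == 1
        assert df.loc["downstream", "count"] == 1
        assert df["percent"].sum() == pytest.approx(100.0)

    def test_strand_awareness(self):
        genes = [GeneModel("g", "chr1", 10_000, 12_000, "-")]  # TSS at 11_999
        regions = self.make_regions([12_500])  # 501 bp upstream for minus strand
        df = cons.tss_distribution(regions, genes)
        assert df.loc["upstream_0_1000", "count"] == 1

    def test_empty_inputs_rejected(self):
        genes = [GeneModel("g", "chr1", 10_000, 12_000, "+")]
        with pytest.raises(ValueError):
            cons.tss_distribution([], genes)
        with pytest.raises(ValueError):
            cons.tss_distribution(self.make_regions([100]), [])

    def test_profile_peaks_at_tss_and_is_strand_aware(self):
        track = track_from([("chr1", 9_900, 10_100, 8.0)])
        plus = [GeneModel("g", "chr1", 10_000, 12_000, "+")]
        prof = cons.tss_profile(track, plus, window=(-1000, 1000), binsize=100)
        assert prof.loc[0, "mean_cpm"] == pytest.approx(8.0)
        assert prof.loc[-1000, "mean_cpm"] == 0.0
        # mirrored gene sees the same profile
        track_m = track_from([("chr1", 11_900, 12_100, 8.0)])
        minus = [GeneModel("g", "chr1", 10_000, 12_000, "-")]
        prof_m = cons.tss_profile(track_m, minus, window=(-1000, 1000), binsize=100)
        assert prof_m.loc[-100, "mean_cpm"] == pytest.approx(prof.loc[-100, "mean_cpm"])

    def test_profile_excludes_off_chromosome_bins(self):
        track = track_from([("chr1", 0, 2_000, 1.0)])
        genes = [GeneModel("g", "chr1", 500, 2_000, "+")]
        prof = cons.tss_profile(track, genes, window=(-1000, 1000), binsize=100,
                                chrom_sizes={"chr1": 2_000})
        assert prof.loc[-1000, "n_genes"] == 0
        assert np.isnan(prof.loc[-1000, "mean_cpm"])
        assert prof.loc[0, "n_genes"] == 1

    def test_profile_window_validation(self):
        track = track_from([("chr1", 0, 100, 1.0)])
        genes = [GeneModel("g", "chr1", 500, 900, "+")]
        with pytest.raises(ValueError):
            cons.tss_profile(track, genes, window=(100, 1000))
        with pytest.raises(ValueError):
            cons.tss_profile(track, genes, window=(-1000, 1000), binsize=300)


def test_end_to_end_consensus_recovers_planted_regions(small_spec, small_study):
    per_genotype = {
        g: cons.replicate_consensus(*reps)
        for g, reps in small_study.replicate_peaks.items()
    }
    regions = cons.build_consensus(per_genotype)
    qpass = cons.genotype_qpass(regions, small_study.replicate_peaks)
    matrix = cons.build_matrix(regions, small_study.tracks)
    kept = cons.confidence_filter(
        regions, matrix, qpass, small_study.sample_genotypes, min_cpm=3.0
    )
    truth = merge(list(small_study.true_ths))
    # every true THS is recovered by some confident region and few extras remain
    recovered = intersect([c.interval for c in kept], truth)
    true_mass = sum(len(iv) for iv in truth)
    assert sum(len(iv) for iv in recovered) >= 0.9 * true_mass
    assert len(kept) <= 1.1 * len(truth)
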