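"""Promoters, enhancers, functional p53 sites, and target assignment."""

import numpy as np
import pandas as pd
import pytest

from tempo3d.grid import AnnotatedGene, Interval
from tempo3d.io import InteractionRecord, read_bed, read_genes_bed, read_interactions
from tempo3d.regulome import (
    PATTERN_CLUSTER_IDS,
    assign_targets,
    assignments_to_frame,
    call_enhancers,
    classify_priming,
    classify_sites,
    define_promoters,
    functional_sites,
    interaction_dynamics,
    log2fc,
    size_factors_background,
    FunctionalP53Site,
)

TPS = ("0h", "1h", "10h")


class TestDefinePromoters:
    def test_plus_strand_window(self):
        (p,) = define_promoters([AnnotatedGene("G", "chr1", 10_000, "+")])
        assert (p.window.start, p.window.end) == (9_000, 10_200)

    def test_minus_strand_window_is_mirrored(self):
        (p,) = define_promoters([AnnotatedGene("G", "chr1", 10_000, "-")])
        assert (p.window.start, p.window.end) == (9_800, 11_000)

    def test_window_clipped_at_chromosome_edges(self):
        (p,) = define_promoters([AnnotatedGene("G", "chr1", 500, "+")])
        assert (p.window.start, p.window.end) == (0, 700)
        (q,) = define_promoters(
            [AnnotatedGene("G", "chr1", 900, "-")], chromsizes={"chr1": 1_000}
        )
        assert (q.window.start, q.window.end) == (700, 1_000)

    def test_first_annotated_tss_wins_for_recurring_gene_ids(self):
        genes = [
            AnnotatedGene("G", "chr1", 5_000, "+"),
            AnnotatedGene("G", "chr1", 9_000, "+"),
        ]
        promoters = define_promoters(genes)
        assert len(promoters) == 1 and promoters[0].tss == 5_000


class TestCallEnhancers:
    def test_intersection_and_per_time_point_states(self):
        k4 = {tp: [Interval("chr1", 0, 1000)] for tp in TPS}
        k27 = {"0h": [], "1h": [Interval("chr1", 500, 1500)], "10h": []}
        (e,) = call_enhancers(k4, k27, [], time_points=TPS)
        assert (e.interval.start, e.interval.end) == (500, 1000)
        assert [e.state(tp) for tp in TPS] == ["primed", "active", "primed"]

    def test_k4me1_only_then_both_marks(self):
        k4 = {"0h": [Interval("chr1", 0, 1000)], "1h": [Interval("chr1", 0, 1000)], "10h": []}
        k27 = {"0h": [], "1h": [Interval("chr1", 0, 1000)], "10h": []}
        (e,) = call_enhancers(k4, k27, [], time_points=TPS)
        assert e.state("0h") == "primed" and e.state("1h") == "active"
        assert e.state("10h") == "absent"

    def test_promoter_overlap_by_one_bp_removes_element(self):
        k4 = {tp: [Interval("chr1", 0, 1000)] for tp in TPS}
        k27 = {tp: [Interval("chr1", 0, 1000)] for tp in TPS}
        (gene,) = [AnnotatedGene("G", "chr1", 1_999, "+")]
        promoters = define_promoters([gene])  # window [999, 2199)
        assert promoters[0].window.start == 999
        assert call_enhancers(k4, k27, promoters, time_points=TPS) == []

    def test_consensus_is_merged_union_across_time_points(self):
        k4 = {
            "0h": [Interval("chr1", 0, 600)],
            "1h": [Interval("chr1", 400, 1000)],
            "10h": [],
        }
        k27 = {"0h": [Interval("chr1", 0, 600)], "1h": [Interval("chr1", 400, 1000)], "10h": []}
        (e,) = call_enhancers(k4, k27, [], time_points=TPS)
        assert (e.interval.start, e.interval.end) == (0, 1000)


class TestFunctionalSites:
    def test_abutting_peak_is_not_functional(self):
        sites = functional_sites(
            [Interval("chr1", 0, 100)], {"1h": [Interval("chr1", 100, 200)], "10h": []}
        )
        assert sites == []

    def test_support_records_which_time_points_overlap(self):
        (s,) = functional_sites(
            [Interval("chr1", 0, 100)],
            {"1h": [], "10h": [Interval("chr1", 99, 200)]},
        )
        assert s.support == ("10h",)

    def test_counts_match_brute_force_overlap(self):
        rng = np.random.default_rng(0)
        peaks = [Interval("chr1", int(s), int(s) + 200) for s in rng.integers(0, 50_000, 5) * 10]
        k27 = [Interval("chr1", 20_000, 120_000)]
        expected = sum(
            1 for p in peaks if min(p.end, 120_000) - max(p.start, 20_000) >= 1
        )
        got = functional_sites(peaks, {"1h": k27, "10h": []})
        assert len(got) == expected


class TestClassifySites:
    def setup_method(self):
        genes = [AnnotatedGene("G1", "chr1", 10_000, "+")]
        self.promoters = define_promoters(genes)
        k4 = {tp: [Interval("chr1", 50_000, 51_000)] for tp in TPS}
        k27 = {"0h": [], "1h": [Interval("chr1", 50_000, 51_000)], "10h": []}
        self.enhancers = call_enhancers(k4, k27, self.promoters, time_points=TPS)
        k4b = {"0h": [Interval("chr1", 70_000, 71_000)], "1h": [], "10h": []}
        k27b = {"0h": [Interval("chr1", 70_000, 71_000)], "1h": [], "10h": []}
        self.enhancers += call_enhancers(k4b, k27b, self.promoters, time_points=TPS)

    def site(self, start, end):
        return FunctionalP53Site(Interval("chr1", start, end), ("1h",))

    def test_promoter_takes_precedence_over_enhancer(self):
        # overlaps both the promoter window [9000,10200) and an enhancer
        s = FunctionalP53Site(Interval("chr1", 9_500, 50_500), ("1h",))
        (out,) = classify_sites([s], self.promoters, self.enhancers)
        assert out.site_class == "promoter-bound"

    def test_active_enhancer_overlap_is_enhancer_bound(self):
        (out,) = classify_sites([self.site(50_200, 50_400)], self.promoters, self.enhancers)
        assert out.site_class == "enhancer-bound"

    def test_element_active_only_at_baseline_does_not_count(self):
        (out,) = classify_sites([self.site(70_200, 70_400)], self.promoters, self.enhancers)
        assert out.site_class == "other-distal"

    def test_no_overlap_is_other_distal(self):
        (out,) = classify_sites([self.site(90_000, 90_100)], self.promoters, self.enhancers)
        assert out.site_class == "other-distal"


def bins_of(n, width=10_000):
    return [Interval("chr1", i * width, (i + 1) * width) for i in range(n)]


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = size_factors_background(counts, bins_of(3), [])
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_recovers_ratio_two(self):
        base = np.array([10.0, 14, 22, 35, 50])
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        sf = size_factors_background(counts, bins_of(5), [])
        # median-of-ratios by hand: geometric mean sqrt(2)*base,
        # ratios 1/sqrt(2) and sqrt(2) for every bin
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_enriched_bins_are_excluded_from_background(self):
        base = np.array([10.0, 14, 22, 35, 50])
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        counts.iloc[0] = [1000, 1000]  # enriched bin would distort the ratio
        enriched = [Interval("chr1", 0, 10_000)]
        sf = size_factors_background(counts, bins_of(5), enriched)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_all_zero_sample_is_an_error(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [0, 0]})
        with pytest.raises(ValueError):
            size_factors_background(counts, bins_of(2), [])

    def test_no_background_left_is_an_error(self):
        counts = pd.DataFrame({"a": [10], "b": [12]})
        with pytest.raises(ValueError, match="background"):
            size_factors_background(counts, bins_of(1), [Interval("chr1", 0, 10_000)])


class TestLog2fc:
    def factors(self):
        return pd.Series({"a1": 1.0, "a2": 1.0, "b1": 1.0, "b2": 1.0})

    def test_equal_means_give_zero(self):
        counts = pd.DataFrame({"a1": [5], "a2": [7], "b1": [6], "b2": [6]})
        fc = log2fc(counts, self.factors(), ["a1", "a2"], ["b1", "b2"])
        assert fc.iloc[0] == 0.0

    def test_hand_computed_fold_change_with_pseudocount(self):
        counts = pd.DataFrame({"a1": [3], "a2": [3], "b1": [15], "b2": [15]})
        fc = log2fc(counts, self.factors(), ["a1", "a2"], ["b1", "b2"])
        assert fc.iloc[0] == pytest.approx(np.log2(16 / 4)) == pytest.approx(2.0)

    def test_all_zero_counts_give_zero(self):
        counts = pd.DataFrame({"a1": [0], "a2": [0], "b1": [0], "b2": [0]})
        fc = log2fc(counts, self.factors(), ["a1", "a2"], ["b1", "b2"])
        assert fc.iloc[0] == 0.0


def interaction(bait_gene, tss, oe_start, oe_end, scores):
    return InteractionRecord(
        Interval("chr1", tss - 1000, tss + 1000),
        Interval("chr1", oe_start, oe_end),
        (bait_gene,),
        dict(zip(TPS, scores)),
    )


class TestAssignTargets:
    def setup_method(self):
        self.genes = [
            AnnotatedGene("GA", "chr1", 1_116_000, "+"),
            AnnotatedGene("GB", "chr1", 1_300_000, "+"),
            AnnotatedGene("GC", "chr1", 1_500_000, "+"),
        ]
        self.promoters = define_promoters(self.genes)
        k4 = {tp: [Interval("chr1", 999_500, 1_000_500)] for tp in TPS}
        k27 = {"0h": [], "1h": [Interval("chr1", 999_500, 1_000_500)], "10h": []}
        self.enhancers = call_enhancers(k4, k27, self.promoters, time_points=TPS)
        site = FunctionalP53Site(Interval("chr1", 999_900, 1_000_100), ("1h",), "enhancer-bound")
        self.sites = [site]

    def assign(self, interactions, lfc):
        return assign_targets(
            self.sites, self.promoters, self.enhancers, interactions, lfc, "1h",
            genes=self.genes,
        )

    def test_largest_log2fc_candidate_wins(self):
        inter = [
            interaction("GA", 1_116_000, 999_000, 1_001_000, (1, 7, 6)),
            interaction("GB", 1_300_000, 999_000, 1_001_000, (1, 6, 6)),
        ]
        out = self.assign(inter, {"GA": 1.4, "GB": 0.2})
        assert [a.gene_id for a in out] == ["GA"]
        assert out[0].distance == 116_000  # |1,000,000 - 1,116,000|

    def test_exact_ties_are_all_retained(self):
        inter = [
            interaction("GA", 1_116_000, 999_000, 1_001_000, (1, 7, 6)),
            interaction("GB", 1_300_000, 999_000, 1_001_000, (1, 6, 6)),
        ]
        out = self.assign(inter, {"GA": 0.8, "GB": 0.8})
        assert sorted(a.gene_id for a in out) == ["GA", "GB"]

    def test_threshold_filters_candidates(self):
        inter = [interaction("GA", 1_116_000, 999_000, 1_001_000, (1, 4.9, 6))]
        assert self.assign(inter, {"GA": 1.0}) == []

    def test_site_without_interactions_yields_nothing(self):
        inter = [interaction("GA", 1_116_000, 2_000_000, 2_002_000, (1, 7, 6))]
        assert self.assign(inter, {"GA": 1.0}) == []

    def test_raising_threshold_never_adds_assignments(self):
        rng = np.random.default_rng(1)
        inter = [
            interaction("GA", 1_116_000, 999_000, 1_001_000, tuple(rng.uniform(0, 10, 3)))
            for _ in range(10)
        ]
        lfc = {"GA": 1.0}
        counts = []
        for thr in (3.0, 5.0, 7.0, 9.0):
            out = assign_targets(
                self.sites, self.promoters, self.enhancers, inter, lfc, "1h",
                threshold=thr,
            )
            counts.append(len(out))
        assert counts == sorted(counts, reverse=True)

    def test_no_gene_is_both_proximal_and_distal(self):
        prox_site = FunctionalP53Site(
            Interval("chr1", 1_115_500, 1_115_700), ("1h",), "promoter-bound"
        )
        inter = [interaction("GA", 1_116_000, 1_115_000, 1_116_500, (6, 7, 6))]
        out = assign_targets(
            [prox_site], self.promoters, self.enhancers, inter, {"GA": 1.0}, "1h",
        )
        assert [(a.gene_id, a.mode) for a in out] == [("GA", "proximal")]


class TestClassifyPriming:
    def make_assignment(self, scores):
        site = FunctionalP53Site(Interval("chr1", 999_900, 1_000_100), ("1h",), "enhancer-bound")
        inter = [interaction("GA", 1_116_000, 999_000, 1_001_000, scores)]
        genes = [AnnotatedGene("GA", "chr1", 1_116_000, "+")]
        promoters = define_promoters(genes)
        out = assign_targets([site], promoters, [], inter, {"GA": 1.0}, "1h")
        return classify_priming(out, inter)

    def test_significant_at_baseline_is_primed(self):
        (a,) = self.make_assignment((6.2, 7.0, 1.0))
        assert a.primed is True

    def test_below_threshold_at_baseline_is_neo_loop(self):
        (a,) = self.make_assignment((3.1, 7.0, 1.0))
        assert a.primed is False


class TestInteractionDynamics:
    def rec(self, scores, oe=2_000_000):
        return interaction("GX", 1_000_000, oe, oe + 2000, scores)

    def test_boundary_score_five_counts_as_gained(self):
        df = interaction_dynamics([self.rec((4.9, 5.0, 1.0))], TPS)
        assert df.loc[0, "0h->1h"] == "gained"

    def test_always_significant_is_maintained_everywhere(self):
        df = interaction_dynamics([self.rec((6, 7, 8))], TPS)
        assert df.loc[0, "0h->1h"] == df.loc[0, "1h->10h"] == "maintained"
        assert df.loc[0, "cluster"] == PATTERN_CLUSTER_IDS[(1, 1, 1)]

    def test_seven_patterns_make_seven_clusters(self):
        patterns = sorted(p for p in np.ndindex(2, 2, 2) if any(p))
        recs = []
        for k, p in enumerate(patterns * 2):  # 14 records, all 7 patterns
            scores = tuple(7.0 + k * 0.1 if bit else 1.0 + k * 0.1 for bit in p)
            recs.append(self.rec(scores, oe=2_000_000 + 10_000 * k))
        df = interaction_dynamics(recs, TPS)
        assert df["cluster"].nunique() == 7
        assert set(df["cluster"]) == {f"C{i}" for i in range(1, 8)}
        # within-pattern ordering assigned to every clustered record
        assert (df["within_order"] >= 0).all()

    def test_never_significant_records_get_no_cluster(self):
        df = interaction_dynamics([self.rec((1, 2, 3))], TPS)
        assert df.loc[0, "cluster"] is None


class TestGoldenRegulome:
    def test_toy_fixture_reproduces_golden_assignment_table(self, data_dir):
        genes = read_genes_bed(data_dir / "genes.bed")
        promoters = define_promoters(genes)
        k4 = {tp: read_bed(data_dir / f"k4me1_{tp}.bed") for tp in TPS}
        k27 = {tp: read_bed(data_dir / f"k27ac_{tp}.bed") for tp in TPS}
        p53 = read_bed(data_dir / "p53_peaks.bed")
        inter = read_interactions(data_dir / "interactions.tsv")
        lfc = (
            pd.read_csv(data_dir / "promoter_log2fc.tsv", sep="\t")
            .set_index("gene_id")["log2fc"]
            .to_dict()
        )
        sites = functional_sites(p53, k27)
        enhancers = call_enhancers(k4, k27, promoters, time_points=TPS)
        classified = classify_sites(sites, promoters, enhancers)
        assignments = classify_priming(
            assign_targets(
                classified, promoters, enhancers, inter, lfc, "1h", genes=genes
            ),
            inter,
        )
        got = assignments_to_frame(assignments).to_csv(sep="\t", index=False)
        golden = (data_dir / "golden_assignments.tsv").read_text()
        assert got == golden
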