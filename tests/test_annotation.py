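import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fivec_locus import annotation as ann
from fivec_locus.io_formats import GenomicInterval, Probe, ProbeMap
from fivec_locus.tad_calling import TadSet


def iv(start, end, name=""):
    return GenomicInterval("chr3", start, end, name)


class TestMergePeaks:
    def test_gap_within_threshold_merges(self):
        merged = ann.merge_peaks([iv(1000, 2000), iv(6000, 7000)], max_gap=5000)
        assert [(m.start, m.end) for m in merged] == [(1000, 7000)]

    def test_gap_beyond_threshold_stays_separate(self):
        merged = ann.merge_peaks([iv(1000, 2000), iv(7001, 8000)], max_gap=5000)
        assert len(merged) == 2

    def test_single_peak_identity(self):
        merged = ann.merge_peaks([iv(10, 20)])
        assert [(m.start, m.end) for m in merged] == [(10, 20)]

    intervals_strategy = st.lists(
        st.tuples(st.integers(0, 10_000), st.integers(1, 500)).map(
            lambda t: iv(t[0], t[0] + t[1])
        ),
        min_size=1, max_size=15,
    )

    @given(peaks=intervals_strategy, gap=st.sampled_from([0, 100, 1000, 5000]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_order_invariant(self, peaks, gap):
        once = ann.merge_peaks(peaks, gap)
        assert ann.merge_peaks(once, gap) == once
        assert ann.merge_peaks(list(reversed(peaks)), gap) == once

    @given(peaks=intervals_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_gap(self, peaks):
        # a larger gap can only coarsen the partition
        fine = ann.merge_peaks(peaks, 100)
        coarse = ann.merge_peaks(peaks, 2000)
        assert len(coarse) <= len(fine)
        for f in fine:
            assert any(c.start <= f.start and f.end <= c.end for c in coarse)


class TestCallEnhancers:
    def test_paired_marks_within_2kb(self):
        enh = ann.call_enhancers([iv(1000, 7000)], [iv(7500, 8000)])
        assert len(enh) == 1
        assert (enh[0].interval.start, enh[0].interval.end) == (1000, 8000)
        assert enh[0].enhancer_id == "E1"

    def test_marks_3kb_apart_no_enhancer(self):
        assert ann.call_enhancers([iv(1000, 2000)], [iv(5000, 6000)]) == []

    def test_overlapping_candidates_unioned(self):
        # one K27ac pairs with two K4me1 regions; union -> one enhancer
        enh = ann.call_enhancers(
            [iv(0, 1000), iv(9000, 10_000)], [iv(2000, 8000)]
        )
        assert len(enh) == 1
        assert (enh[0].interval.start, enh[0].interval.end) == (0, 10_000)

    def test_ids_ordered_by_coordinate(self):
        enh = ann.call_enhancers(
            [iv(50_000, 51_000), iv(1_000, 2_000)],
            [iv(51_500, 52_000), iv(2_500, 3_000)],
        )
        assert [e.enhancer_id for e in enh] == ["E1", "E2"]
        assert enh[0].interval.start < enh[1].interval.start


class TestClusterEnhancers:
    def _enh(self, start, end, eid):
        return ann.Enhancer(iv(start, end, eid), eid, iv(start, end), iv(start, end))

    def test_9kb_apart_clusters(self):
        e = [self._enh(0, 1000, "E1"), self._enh(10_000, 11_000, "E2")]
        assignment = ann.cluster_enhancers(e, max_gap=10_000)
        assert assignment["E1"] == assignment["E2"] == "E1/E2"

    def test_exactly_10kb_apart_separate(self):
        e = [self._enh(0, 1000, "E1"), self._enh(11_000, 12_000, "E2")]
        assignment = ann.cluster_enhancers(e, max_gap=10_000)
        assert assignment["E1"] == "E1" and assignment["E2"] == "E2"

    def test_run_of_four_labelled_with_range(self):
        e = [self._enh(i * 5000, i * 5000 + 1000, f"E{i + 4}") for i in range(4)]
        assignment = ann.cluster_enhancers(e, max_gap=10_000)
        assert set(assignment.values()) == {"E4-E7"}

    def test_empty_input(self):
        assert ann.cluster_enhancers([]) == {}


@pytest.fixture(scope="module")
def toy_map():
    probes = [
        Probe("F1", "forward", "chr3", 0, 4_000),
        Probe("R1", "reverse", "chr3", 20_000, 24_000),
        Probe("F2", "forward", "chr3", 600_000, 604_000),
        Probe("R2", "reverse", "chr3", 900_000, 904_000),
    ]
    return ProbeMap(probes)


def loops_frame(pairs, pm):
    rows = []
    for f, r in pairs:
        rows.append({
            "fwd_id": f, "rev_id": r, "chrom": "chr3",
            "fwd_mid": pm[f].midpoint, "rev_mid": pm[r].midpoint,
            "distance_bp": abs(pm[f].midpoint - pm[r].midpoint),
            "obs": 5.0, "q": 0.01, "significant": True,
        })
    return pd.DataFrame(rows)


class TestClassifyByPromoter:
    def test_no_tss_all_nn(self, toy_map):
        loops = loops_frame([("F1", "R1")], toy_map)
        counts, labels = ann.classify_by_promoter(
            loops, toy_map, pd.DataFrame({"gene_id": [], "chrom": [], "tss": []})
        )
        assert counts == {"PP": 0, "PN": 0, "NN": 1}
        assert list(labels) == ["NN"]

    def test_distance_arithmetic_pn(self, toy_map):
        # TSS 500 bp past F1's fragment end -> promoter; 6 kb past R1 -> not
        tss = pd.DataFrame(
            {"gene_id": ["a", "b"], "chrom": ["chr3"] * 2, "tss": [4_500, 30_000]}
        )
        counts, labels = ann.classify_by_promoter(
            loops_frame([("F1", "R1")], toy_map), toy_map, tss, window=5_000
        )
        assert list(labels) == ["PN"]
        assert counts == {"PP": 0, "PN": 1, "NN": 0}

    def test_percentages_sum_to_100(self):
        pct = ann.promoter_class_percentages({"PP": 300, "PN": 539, "NN": 300})
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.02)


class TestIntraInterTad:
    def test_reported_percentages_match_worked_example(self):
        out = ann.intra_inter_summary(n_intra=340, n_inter=799)
        assert out["pct_inter"] == 70.15
        assert out["pct_intra"] == 29.85

    def test_single_tad_all_intra(self, toy_map):
        tads = TadSet([iv(0, 1_000_000, "TAD1")])
        loops = loops_frame([("F1", "R1"), ("F2", "R2")], toy_map)
        labels, summary = ann.label_intra_inter_tad(loops, tads, toy_map)
        assert set(labels) == {"intra"}
        assert summary["pct_intra"] == 100.0

    def test_boundary_between_anchors_is_inter(self, toy_map):
        tads = TadSet([iv(0, 500_000, "TAD1"), iv(500_000, 1_000_000, "TAD2")])
        loops = loops_frame([("F1", "R2"), ("F1", "R1")], toy_map)
        labels, summary = ann.label_intra_inter_tad(loops, tads, toy_map)
        assert list(labels) == ["inter", "intra"]
        assert summary["n_intra"] == 1 and summary["n_inter"] == 1


class TestEnhancerNetwork:
    def test_enhancer_window_threshold(self, toy_map):
        tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr3"], "tss": [902_000]})
        loops = loops_frame([("F2", "R2")], toy_map)
        # enhancer 8 kb from F2's fragment -> assigned
        e_near = ann.call_enhancers([iv(612_000, 613_000)], [iv(613_500, 614_000)])
        net = ann.assign_enhancer_network(loops, e_near, toy_map, tss)
        assert len(net) == 1
        assert net["target_gene"].iloc[0] == "g"
        # enhancer 12 kb away -> not assigned
        e_far = ann.call_enhancers([iv(616_000, 617_000)], [iv(617_500, 618_000)])
        assert len(ann.assign_enhancer_network(loops, e_far, toy_map, tss)) == 0

    def test_closest_tss_chosen(self, toy_map):
        tss = pd.DataFrame(
            {"gene_id": ["far", "near"], "chrom": ["chr3"] * 2,
             "tss": [911_000, 907_000]}
        )
        loops = loops_frame([("F2", "R2")], toy_map)
        enh = ann.call_enhancers([iv(600_500, 601_000)], [iv(601_200, 602_000)])
        net = ann.assign_enhancer_network(loops, enh, toy_map, tss)
        assert net["target_gene"].iloc[0] == "near"

    def test_loop_without_enhancer_absent(self, toy_map):
        loops = loops_frame([("F1", "R1")], toy_map)
        enh = ann.call_enhancers([iv(600_500, 601_000)], [iv(601_200, 602_000)])
        net = ann.assign_enhancer_network(
            loops, enh, toy_map, pd.DataFrame({"gene_id": [], "chrom": [], "tss": []})
        )
        assert len(net) == 0

    def test_involvement_summary_floors_percentages(self):
        # 252/1139 -> 22%; 144/273 -> 52% (floor to integer percent)
        network = pd.DataFrame({
            "loop_index": np.arange(273),
            "target_gene": ["g"] * 144 + ["non-promoter"] * 129,
        })
        network["loop_index"] = np.concatenate(
            [np.arange(252), np.arange(21)]  # 252 unique loops over 273 rows
        )
        out = ann.enhancer_involvement_summary(network, n_loops_total=1139)
        assert out["pct_loops_enhancer"] == 22
        assert out["n_loops_enhancer"] == 252
        assert out["pct_rows_promoter_target"] == 52
        assert out["n_rows_promoter_target"] == 144


class TestScalingCurve:
    def test_single_distance_single_bin(self):
        df = ann.scaling_curve([50_000] * 5, [1, 2, 3, 4, 5], ["intra"] * 5)
        assert len(df) == 1
        assert df["mean_value"].iloc[0] == pytest.approx(3.0)

    def test_classes_partition_and_bounds(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1e4, 1e6, 100)
        labels = np.where(d < 5e5, "intra", "inter")
        df = ann.scaling_curve(d, np.ones(100), labels, n_bins=8)
        assert set(df["class"]) == {"intra", "inter"}
        intra_max = df[df["class"] == "intra"]["bin_hi"].max()
        assert d[labels == "intra"].max() <= intra_max


class TestCountTadsSpanned:
    TADS = [iv(0, 1000, "T1"), iv(1000, 2000, "T2"), iv(2000, 3000, "T3")]

    def test_locus_inside_one_tad(self):
        assert ann.count_tads_spanned(iv(100, 900), self.TADS) == 1

    def test_locus_straddling_boundary(self):
        assert ann.count_tads_spanned(iv(900, 1100), self.TADS) == 2

    def test_locus_exactly_matching_tad(self):
        assert ann.count_tads_spanned(iv(1000, 2000), self.TADS) == 1

    def test_absent_chromosome_warns_zero(self):
        locus = GenomicInterval("chrX", 0, 100)
        with pytest.warns(UserWarning, match="chrX"):
            assert ann.count_tads_spanned(locus, self.TADS) == 0
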