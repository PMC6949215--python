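"""Categorical array calling: thresholds, gene calls, focal rescue."""

import numpy as np
import pytest

from cnaconcord.array_calls import (
    CallThresholds,
    CNAState,
    SubState,
    focal_rescue,
    gene_call,
    state_of_segment,
)
from cnaconcord.intervals import GeneRegion, GenomicInterval
from cnaconcord.segmentation import Segment, SegmentationParams, segment

from conftest import make_profile

T = CallThresholds()  # loss_max -0.2, deletion_max -0.8, gain_min 0.15, amp_min 0.7


def seg(start, end, mean):
    return Segment(start, end, mean)


class TestStateOfSegment:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (0.0, CNAState.NORMAL),
            (-0.2, CNAState.LOSS_DELETION),  # boundary inclusive toward abnormal
            (0.15, CNAState.GAIN_AMPLIFICATION),
            (-0.19, CNAState.NORMAL),
            (-1.0, CNAState.LOSS_DELETION),
            (0.9, CNAState.GAIN_AMPLIFICATION),
        ],
    )
    def test_threshold_boundaries(self, mean, expected):
        assert state_of_segment(seg(0, 10, mean), T) is expected

    def test_deep_loss_is_deletion_substate(self):
        region = GeneRegion("G", GenomicInterval("chr1", 0, 10_000))
        probes = make_profile(np.zeros(10)).probes
        call = gene_call([seg(0, 10, -1.0)], region, probes, T)
        assert call.state is CNAState.LOSS_DELETION
        assert call.sub_state is SubState.DELETION

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            CallThresholds(loss_max=-0.9, deletion_max=-0.2)


class TestGeneCall:
    def make_region(self):
        span = GenomicInterval("chr1", 20_000, 80_000, "GENE")
        exons = tuple(
            GenomicInterval("chr1", 20_000 + k * 8_000, 21_000 + k * 8_000, str(k + 1))
            for k in range(8)
        )
        return GeneRegion("GENE", span, exons)

    def test_all_normal_segments_give_normal(self):
        probes = make_profile(np.zeros(100)).probes
        call = gene_call([seg(0, 100, 0.01)], self.make_region(), probes, T)
        assert call.state is CNAState.NORMAL
        assert call.provenance == "cbs"

    def test_deletion_reports_exon_extent(self):
        # deletion covering the exon 4-7 analogues (probes 44..69)
        probes = make_profile(np.zeros(100)).probes
        segments = [seg(0, 44, 0.0), seg(44, 70, -1.0), seg(70, 100, 0.0)]
        call = gene_call(segments, self.make_region(), probes, T)
        assert call.state is CNAState.LOSS_DELETION
        assert (call.exon_first, call.exon_last) == ("4", "7")

    def test_nested_gain_beats_shallower_nested_deletion(self):
        # copy 3.6 gain vs copy 1.1 nested deletion: the gain is further
        # from baseline in copy space and wins, although its |mean LRR|
        # is slightly smaller
        gain_lrr = np.log2(3.6 / 2)  # +0.848
        del_lrr = np.log2(1.1 / 2)  # -0.862
        probes = make_profile(np.zeros(100)).probes
        segments = [
            seg(0, 20, 0.0),
            seg(20, 40, gain_lrr),
            seg(40, 50, del_lrr),
            seg(50, 70, gain_lrr),
            seg(70, 100, 0.0),
        ]
        call = gene_call(segments, self.make_region(), probes, T)
        assert call.state is CNAState.GAIN_AMPLIFICATION

    def test_short_segments_ignored(self):
        probes = make_profile(np.zeros(100)).probes
        segments = [seg(0, 48, 0.0), seg(48, 51, -1.0), seg(51, 100, 0.0)]
        call = gene_call(segments, self.make_region(), probes, T, min_markers=5)
        assert call.state is CNAState.NORMAL

    def test_wrong_chromosome_rejected(self):
        probes = make_profile(np.zeros(10), chrom="chr2").probes
        with pytest.raises(ValueError, match="chr"):
            gene_call([seg(0, 10, 0.0)], self.make_region(), probes, T)

    def test_normal_everywhere_normal_for_random_regions(self):
        rng = np.random.default_rng(5)
        probes = make_profile(np.zeros(100)).probes
        segments = [seg(0, 100, 0.05)]
        for _ in range(20):
            a, b = sorted(rng.integers(0, 99_000, 2))
            region = GeneRegion("R", GenomicInterval("chr1", int(a), int(b) + 1000))
            assert gene_call(segments, region, probes, T).state is CNAState.NORMAL

    def test_loss_threshold_monotonicity(self):
        """Relaxing loss_max toward 0 can only create losses, never remove."""
        probes = make_profile(np.zeros(60)).probes
        region = GeneRegion("G", GenomicInterval("chr1", 0, 60_000))
        segments = [seg(0, 30, -0.1), seg(30, 60, -0.3)]
        states = []
        for loss_max in (-0.35, -0.25, -0.15, -0.05):
            t = CallThresholds(loss_max=loss_max, deletion_max=-0.9)
            states.append(gene_call(segments, region, probes, t).state.abnormal)
        assert states == sorted(states)  # False..True, no reversal


class TestFocalRescue:
    def hole_region(self):
        """Gene with a probe hole; probes exist at 0..29k and 72k..99k."""
        span = GenomicInterval("chr1", 0, 100_000, "GENE")
        exons = tuple(
            GenomicInterval("chr1", s, s + 1_000, str(k + 1))
            for k, s in enumerate(range(2_000, 98_000, 12_000))
        )
        return GeneRegion("GENE", span, exons)

    def hole_profile(self, lrr_by_pos):
        from cnaconcord.intervals import ArrayProbe
        from cnaconcord.segmentation import ArrayProfile

        positions = [p for p in range(0, 100_000, 1_000) if not 30_000 <= p < 72_000]
        probes = tuple(
            ArrayProbe(f"p{pos}", GenomicInterval("chr1", pos, pos + 1))
            for pos in positions
        )
        lrr = np.array([lrr_by_pos(p) for p in positions])
        return ArrayProfile("s1", "chr1", probes, lrr)

    def test_rescues_deletion_downstream_of_hole(self):
        rng = np.random.default_rng(13)
        def lrr(pos):
            base = rng.normal(0, 0.1)
            return base - 1.0 if 72_000 <= pos < 84_000 else base

        profile = self.hole_profile(lrr)
        call = focal_rescue(profile, self.hole_region(), T, window_k=4)
        assert call is not None
        assert call.state is CNAState.LOSS_DELETION
        assert call.provenance == "rescue"
        assert call.supporting_interval.start >= 72_000

    def test_clean_profile_no_rescue(self):
        rng = np.random.default_rng(3)
        profile = self.hole_profile(lambda p: rng.normal(0, 0.1))
        assert focal_rescue(profile, self.hole_region(), T) is None

    def test_single_outlier_probe_not_rescued(self):
        profile = self.hole_profile(lambda p: 1.5 if p == 75_000 else 0.0)
        assert focal_rescue(profile, self.hole_region(), T, window_k=2) is None

    def test_false_rescue_rate_under_null(self):
        """At noise sd 0.15 the rescue operator almost never fires on
        event-free data (well under 1% of samples)."""
        rng = np.random.default_rng(77)
        region = GeneRegion("G", GenomicInterval("chr1", 0, 100_000))
        fired = 0
        n = 300
        for _ in range(n):
            profile = make_profile(rng.normal(0, 0.15, 100))
            if focal_rescue(profile, region, T, window_k=4) is not None:
                fired += 1
        assert fired / n <= 0.01

    def test_rescue_is_additive_over_cbs(self):
        """Rescue only adds abnormal calls on top of segmentation output."""
        rng = np.random.default_rng(21)
        region = GeneRegion("G", GenomicInterval("chr1", 0, 100_000))
        params = SegmentationParams(nperm=500, seed=2)
        for r in range(10):
            v = rng.normal(0, 0.15, 100)
            if r % 2:
                v[30:50] -= 1.0
            profile = make_profile(v)
            segs = segment(profile, params)
            cbs = gene_call(segs, region, profile.probes, T, sample_id="s")
            manual = cbs
            if not cbs.state.abnormal:
                rescued = focal_rescue(profile, region, T)
                if rescued is not None:
                    manual = rescued
            assert (not cbs.state.abnormal) or manual.state.abnormal
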