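"""Window-state calling, segmentation, CNVR merging and filtering."""

import numpy as np
import pytest

from rdcnv import calling
from rdcnv.calling import CnvCall, CnvRegion

from conftest import make_matrix


def region(id, chrom, start, end, carriers, type="deletion"):
    return CnvRegion(id=id, chrom=chrom, start=start, end=end, type=type,
                     carriers=carriers, copy_number={})


class TestWindowStates:
    @pytest.mark.parametrize(
        "nd,expected",
        [
            (1.0, calling.NEUTRAL),
            (0.5, calling.HET_DEL),  # bracketed by the 0.2 / 0.7 limits
            (0.19, calling.HOM_DEL),
            (0.20, calling.HET_DEL),  # half-open boundary at the lower limit
            (0.7, calling.NEUTRAL),  # del ceiling is exclusive
            (1.3, calling.NEUTRAL),  # dup floor is exclusive
            (1.31, calling.DUP),
        ],
    )
    def test_state_thresholds(self, nd, expected):
        m = make_matrix(np.full((3, 1), nd))
        states = calling.call_window_states(m)
        assert (states == expected).all()

    def test_masked_windows_get_no_state(self):
        m = make_matrix(np.full((3, 1), 0.5), mask=[True, False, True])
        states = calling.call_window_states(m)
        assert states[1, 0] == calling.MASKED

    def test_threshold_order_validated(self):
        m = make_matrix(np.ones((3, 1)))
        with pytest.raises(ValueError, match="thresholds"):
            calling.call_window_states(m, lower=0.8, del_ceiling=0.7)


class TestSegmentation:
    def test_gap_tolerated_inside_run(self):
        # del, del, neutral, del with max_gap_windows=1 -> one call over all 4
        nd = np.array([[0.5], [0.5], [1.0], [0.5]])
        m = make_matrix(nd)
        calls = calling.segment_sample_cnvs(
            calling.call_window_states(m), m, max_gap_windows=1
        )
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end) == (0, 1600)
        assert c.n_windows == 3  # member windows exclude the neutral gap
        assert c.state == "het_del"

    def test_run_shorter_than_min_windows_dropped(self):
        nd = np.array([[1.0], [1.5], [1.0]])
        m = make_matrix(nd)
        calls = calling.segment_sample_cnvs(
            calling.call_window_states(m), m, min_windows=2
        )
        assert calls == []

    def test_opposite_directions_never_merge(self):
        nd = np.array([[0.5], [0.5], [1.6], [1.6]])
        m = make_matrix(nd)
        calls = calling.segment_sample_cnvs(calling.call_window_states(m), m)
        assert len(calls) == 2
        assert {c.state for c in calls} == {"het_del", "dup"}

    def test_hom_and_het_mix_within_deletion_run(self):
        nd = np.array([[0.1], [0.1], [0.5], [0.5]])
        m = make_matrix(nd)
        calls = calling.segment_sample_cnvs(calling.call_window_states(m), m)
        assert len(calls) == 1
        assert calls[0].state == "het_del"  # mean 0.3 >= lower

    def test_runs_do_not_cross_chromosomes(self):
        import rdcnv.depth as depth

        lay = depth.GenomeLayout(chroms={"c1": 800, "c2": 800},
                                 window_size=400, step=400)
        nd = np.full((4, 1), 0.5)
        m = depth.DepthMatrix(layout=lay, samples=["s1"], raw=nd.copy(),
                              normalized=nd,
                              window_mask=np.ones(4, bool))
        calls = calling.segment_sample_cnvs(calling.call_window_states(m), m)
        assert [c.chrom for c in calls] == ["c1", "c2"]


class TestMerging:
    def test_identical_intervals_merge_to_one_cnvr(self):
        nd = np.ones((6, 4))
        nd[0:2, 0] = 0.5
        nd[0:2, 1] = 0.5
        m = make_matrix(nd)
        calls = [
            CnvCall("s1", "chr1", 0, 800, 0.5, "het_del", 2),
            CnvCall("s2", "chr1", 0, 800, 0.5, "het_del", 2),
        ]
        regions = calling.merge_to_cnvrs(calls, m)
        assert len(regions) == 1
        assert regions[0].n_carriers == 2

    def _two_span_matrix(self, correlated: bool):
        # spans [0,1000) (windows 0-2) and [1300,2300) (windows 3-5),
        # 400 bp non-overlapping windows; per-sample vectors either equal
        # (r=1) or exactly orthogonal (r=0)
        nd = np.ones((6, 4))
        a = np.array([1.0, 1.0, 2.0, 2.0])
        b = a if correlated else np.array([1.0, 2.0, 1.0, 2.0])
        nd[0:3, :] = a
        nd[3:6, :] = b
        return make_matrix(nd)

    def _two_span_calls(self):
        return [
            CnvCall("s1", "chr1", 0, 1000, 2.0, "dup", 3),
            CnvCall("s2", "chr1", 1300, 2300, 2.0, "dup", 3),
        ]

    def test_gap_rule_with_correlation_merges(self):
        # gap 300 < 0.2 x (1000 + 1000) = 400 and r = 1 -> merged
        m = self._two_span_matrix(correlated=True)
        regions = calling.merge_to_cnvrs(self._two_span_calls(), m)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 2300)

    def test_uncorrelated_spans_not_merged(self):
        m = self._two_span_matrix(correlated=False)
        regions = calling.merge_to_cnvrs(self._two_span_calls(), m)
        assert len(regions) == 2

    def test_gap_too_wide_never_merges(self):
        nd = np.ones((8, 4))
        nd[:, 0] = 2.0  # perfectly correlated everywhere
        m = make_matrix(nd)
        calls = [
            CnvCall("s1", "chr1", 0, 800, 2.0, "dup", 2),
            CnvCall("s2", "chr1", 1600, 2400, 2.0, "dup", 2),
        ]  # gap 800 >= 0.2 x 1600 = 320
        regions = calling.merge_to_cnvrs(calls, m)
        assert len(regions) == 2

    def test_few_samples_falls_back_to_gap_only(self, caplog):
        nd = np.ones((6, 2))
        m = make_matrix(nd)
        calls = [
            CnvCall("s1", "chr1", 0, 1000, 2.0, "dup", 3),
            CnvCall("s2", "chr1", 1300, 2300, 2.0, "dup", 3),
        ]
        with caplog.at_level("WARNING"):
            regions = calling.merge_to_cnvrs(calls, m)
        assert len(regions) == 1
        assert "fewer than 4 samples" in caplog.text

    def test_merge_is_fixed_point(self, default_result):
        """Re-merging the merged CNVRs (as single calls) changes nothing."""
        regions = default_result.regions
        matrix = default_result.matrix
        calls = [
            CnvCall(sample=next(iter(r.carriers)), chrom=r.chrom, start=r.start,
                    end=r.end, mean_norm_depth=1.0,
                    state=next(iter(r.carriers.values())), n_windows=2)
            for r in regions
        ]
        remerged = calling.merge_to_cnvrs(calls, matrix)
        assert len(remerged) == len(regions)
        assert sorted((r.chrom, r.start, r.end) for r in remerged) == sorted(
            (r.chrom, r.start, r.end) for r in regions
        )


class TestClassifyAndFilter:
    def test_type_classification(self):
        assert calling.classify_cnvr_type(
            region("r", "c", 0, 800, {"a": "het_del", "b": "hom_del"})
        ) == "deletion"
        assert calling.classify_cnvr_type(
            region("r", "c", 0, 800, {"a": "dup", "b": "dup"})
        ) == "duplication"
        assert calling.classify_cnvr_type(
            region("r", "c", 0, 800, {"a": "het_del", "b": "dup"})
        ) == "mixed"

    def test_neutral_carrier_is_internal_error(self):
        with pytest.raises(ValueError, match="neutral"):
            calling.classify_cnvr_type(
                region("r", "c", 0, 800, {"a": "neutral"})
            )

    def test_min_samples_filter(self):
        regs = [
            region("r1", "chr1", 0, 800, {"a": "dup"}),
            region("r2", "chr1", 0, 800, {"a": "dup", "b": "dup"}),
        ]
        kept = calling.filter_cnvrs(regs, min_samples=2)
        assert [r.id for r in kept] == ["r2"]

    def test_unplaced_scaffolds_removed(self):
        regs = [
            region("r1", "chr1", 0, 800, {"a": "dup", "b": "dup"}),
            region("r2", "scaffold_9", 0, 800, {"a": "dup", "b": "dup"}),
        ]
        kept = calling.filter_cnvrs(regs, placed_chroms=["chr1"])
        assert [r.id for r in kept] == ["r1"]

    def test_empty_input_empty_output(self):
        assert calling.filter_cnvrs([]) == []


class TestRecoveryOnDefaultCohort:
    def test_no_region_below_min_samples_or_off_whitelist(self, default_result):
        for r in default_result.regions:
            assert r.n_carriers >= 2
            assert r.chrom in default_result.matrix.layout.chroms

    def test_type_counts_partition_total(self, default_result):
        counts = {"deletion": 0, "duplication": 0, "mixed": 0}
        for r in default_result.regions:
            counts[r.type] += 1
        assert sum(counts.values()) == len(default_result.regions)

    def test_zero_noise_recovery_exact(self, zero_noise_cohort, zero_noise_matrix):
        """Every planted event with >= 2 carriers is recovered with
        boundary error of at most one window step at zero noise."""
        from rdcnv import simulate

        m = zero_noise_matrix
        states = calling.call_window_states(m)
        calls = calling.segment_sample_cnvs(states, m)
        regions = calling.filter_cnvrs(
            calling.merge_to_cnvrs(calls, m), min_samples=2
        )
        rec = simulate.evaluate_recovery(
            zero_noise_cohort.truth, regions, m.layout
        )
        assert rec["recall"] == 1.0
        assert rec["max_boundary_error"] <= m.layout.step
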