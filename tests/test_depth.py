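"""Window depth counting, GC correction and sample normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rdcnv import depth
from rdcnv.depth import GenomeLayout


def reads_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "length"])


class TestLayout:
    def test_windows_tile_and_truncate(self):
        lay = GenomeLayout(chroms={"chr1": 2000}, window_size=800, step=400)
        assert lay.window_start.tolist() == [0, 400, 800, 1200, 1600]
        assert lay.window_end.tolist() == [800, 1200, 1600, 2000, 2000]

    def test_placed_whitelist_drops_scaffolds(self):
        lay = GenomeLayout.from_chrom_sizes(
            {"chr1": 4000, "scaffold_12": 4000}, placed_chroms=["chr1"]
        )
        assert list(lay.chroms) == ["chr1"]

    def test_window_size_must_be_step_multiple(self):
        with pytest.raises(ValueError):
            GenomeLayout(chroms={"chr1": 4000}, window_size=900, step=400)


class TestWindowDepth:
    def test_midpoint_rule_enumerated(self):
        # one read with midpoint 900: not in [0,800), in [400,1200), and in
        # the truncated terminal window [800,1200)
        lay = GenomeLayout(chroms={"chr1": 1200}, window_size=800, step=400)
        m = depth.compute_window_depth(
            {"s1": reads_df([("chr1", 850, 100)])}, lay
        )
        assert m.raw[:2, 0].tolist() == [0, 1]
        assert m.raw[2, 0] == 1

    def test_midpoint_on_window_start_counted_half_open(self):
        lay = GenomeLayout(chroms={"chr1": 1200}, window_size=800, step=400)
        m = depth.compute_window_depth(
            {"s1": reads_df([("chr1", 350, 100)])}, lay
        )  # midpoint exactly 400
        assert m.raw[:, 0].tolist() == [1, 1, 0]

    def test_empty_reads_error_names_sample(self):
        lay = GenomeLayout(chroms={"chr1": 1200})
        with pytest.raises(ValueError, match="s7"):
            depth.compute_window_depth({"s7": reads_df([])}, lay)

    def test_off_layout_chrom_reads_dropped_and_counted(self):
        lay = GenomeLayout(chroms={"chr1": 1200})
        m = depth.compute_window_depth(
            {"s1": reads_df([("chr1", 0, 100), ("scaffold_1", 0, 100)])}, lay
        )
        assert m.dropped_reads == {"s1": 1}
        assert m.raw.sum() == 1

    def test_total_counts_match_reads(self):
        rng = np.random.default_rng(0)
        lay = GenomeLayout(chroms={"chr1": 20_000}, window_size=800, step=400)
        starts = rng.integers(0, 19_900, size=500)
        m = depth.compute_window_depth(
            {"s1": reads_df([("chr1", int(s), 100) for s in starts])}, lay
        )
        # each read midpoint lies in exactly window_size/step = 2 windows,
        # except midpoints in the first step of the chromosome
        mids = starts + 50
        expected = 2 * len(mids) - (mids < 400).sum()
        assert m.raw.sum() == expected


class TestGcNormalize:
    def test_uniform_gc_is_identity(self):
        lay = GenomeLayout(chroms={"chr1": 40_000}, window_size=800, step=400)
        rng = np.random.default_rng(1)
        raw = rng.poisson(100, size=(lay.n_windows, 2)).astype(float)
        m = depth.DepthMatrix(layout=lay, samples=["a", "b"], raw=raw)
        out = depth.gc_normalize(m, np.full(lay.n_windows, 0.5), n_bins=10)
        np.testing.assert_array_equal(out.gc_corrected, raw)

    def test_two_bin_bias_equalized(self):
        # high-GC windows have exactly twice the depth of low-GC windows;
        # after correction the two bin medians must match
        lay = GenomeLayout(chroms={"chr1": 80_000}, window_size=800, step=400)
        n = lay.n_windows
        gc = np.where(np.arange(n) % 2 == 0, 0.3, 0.6)
        raw = np.where(gc > 0.5, 200.0, 100.0)[:, None]
        m = depth.DepthMatrix(layout=lay, samples=["a"], raw=raw)
        out = depth.gc_normalize(m, gc, n_bins=10, min_bin_windows=5)
        lo = np.median(out.gc_corrected[gc < 0.5, 0])
        hi = np.median(out.gc_corrected[gc > 0.5, 0])
        assert lo == hi

    def test_gc_out_of_range_rejected(self):
        lay = GenomeLayout(chroms={"chr1": 4000})
        m = depth.DepthMatrix(
            layout=lay, samples=["a"], raw=np.ones((lay.n_windows, 1))
        )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            depth.gc_normalize(m, np.full(lay.n_windows, 1.2))

    def test_all_zero_sample_stays_zero_with_warning(self, caplog):
        lay = GenomeLayout(chroms={"chr1": 40_000})
        raw = np.zeros((lay.n_windows, 1))
        m = depth.DepthMatrix(layout=lay, samples=["empty"], raw=raw)
        with caplog.at_level("WARNING"):
            out = depth.gc_normalize(m, np.full(lay.n_windows, 0.5))
        assert (out.gc_corrected == 0).all()
        assert "empty" in caplog.text

    def test_idempotent(self, default_cohort):
        m = depth.compute_window_depth(
            {s: default_cohort.reads[s] for s in list(default_cohort.reads)[:3]},
            default_cohort.layout,
        )
        once = depth.gc_normalize(m, default_cohort.gc_track)
        twice = depth.gc_normalize(
            depth.DepthMatrix(layout=m.layout, samples=m.samples,
                              raw=once.gc_corrected),
            default_cohort.gc_track,
        )
        np.testing.assert_allclose(
            twice.gc_corrected, once.gc_corrected, rtol=1e-12
        )


class TestSampleNormalize:
    def _matrix(self, corrected, gc=None):
        lay = GenomeLayout(
            chroms={"chr1": corrected.shape[0] * 400}, window_size=400, step=400
        )
        m = depth.DepthMatrix(
            layout=lay,
            samples=[f"s{j}" for j in range(corrected.shape[1])],
            raw=corrected.copy(),
            gc=np.full(lay.n_windows, 0.5) if gc is None else gc,
            gc_corrected=corrected,
        )
        return m

    def test_constant_depth_normalizes_to_one(self):
        m = self._matrix(np.full((100, 1), 37.0))
        out = depth.sample_normalize(m)
        np.testing.assert_array_equal(out.normalized, 1.0)

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(2)
        corrected = rng.poisson(100, size=(200, 2)).astype(float) + 1
        base = depth.sample_normalize(self._matrix(corrected.copy()))
        scaled = corrected.copy()
        scaled[:, 1] *= 3.0
        out = depth.sample_normalize(self._matrix(scaled))
        np.testing.assert_allclose(out.normalized, base.normalized, rtol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(min_value=1e-3, max_value=1e3,
                       allow_nan=False, allow_infinity=False))
    def test_scale_invariance_property(self, c):
        rng = np.random.default_rng(3)
        corrected = rng.poisson(80, size=(120, 2)).astype(float) + 1
        base = depth.sample_normalize(self._matrix(corrected.copy()))
        scaled = corrected.copy()
        scaled[:, 0] *= c
        out = depth.sample_normalize(self._matrix(scaled))
        np.testing.assert_allclose(out.normalized, base.normalized, rtol=1e-9)

    def test_zero_median_sample_rejected(self):
        corrected = np.ones((100, 2)) * 50.0
        corrected[:, 0] = 0.0
        with pytest.raises(ValueError, match="s0"):
            depth.sample_normalize(self._matrix(corrected))

    def test_gc_extreme_windows_masked(self):
        corrected = np.full((100, 2), 50.0)
        gc = np.full(100, 0.5)
        gc[:5] = 0.1  # below gc_min
        out = depth.sample_normalize(self._matrix(corrected, gc=gc))
        assert not out.window_mask[:5].any()
        assert out.window_mask[5:].all()

    def test_zero_noise_depth_is_half_copy_number(
        self, zero_noise_cohort, zero_noise_matrix
    ):
        """With expectation-exact counts, normalized depth equals CN/2 on
        every window fully inside or fully outside a planted event."""
        m = zero_noise_matrix
        lay = m.layout
        nd = m.normalized
        expected = np.full_like(nd, 1.0)
        partial = np.zeros(lay.n_windows, bool)
        for t in zero_noise_cohort.truth:
            idx = lay.windows_overlapping(t.chrom, t.start, t.end)
            inside = idx[
                (lay.window_start[idx] >= t.start) & (lay.window_end[idx] <= t.end)
            ]
            partial[np.setdiff1d(idx, inside)] = True
            for s, cn in t.copy_number_by_sample.items():
                expected[inside, m.sample_index(s)] = cn / 2.0
        check = m.window_mask & ~partial
        np.testing.assert_allclose(nd[check, :], expected[check, :], atol=1e-12)
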