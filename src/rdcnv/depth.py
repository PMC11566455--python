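"""Windowed read depth and its normalization.

Depth is summarized in overlapping sliding windows (default 800 bp, step
400 bp). Each read contributes to every window containing its midpoint, so
per-window counts stay Poisson under a uniform read model. Two corrections
bring a diploid window to a depth of 1.0:

1. GC correction — windows are binned by GC fraction and each bin is
   rescaled so its median depth matches the genome-wide median (per sample).
2. Sample scaling — each sample is divided by its own robust baseline
   (median over usable windows), removing library-size differences.

Copy number is then read off as ``2 * normalized depth``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GenomeLayout:
    """Chromosome sizes plus the derived overlapping-window grid.

    Windows start at every multiple of ``step`` and have length
    ``window_size`` (the last windows of a chromosome are truncated at the
    chromosome end). ``window_size`` must be a multiple of ``step``.
    """

    chroms: dict[str, int]
    window_size: int = 800
    step: int = 400
    window_chrom: np.ndarray = field(init=False, repr=False)
    window_start: np.ndarray = field(init=False, repr=False)
    window_end: np.ndarray = field(init=False, repr=False)
    chrom_slices: dict[str, slice] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window_size and step must be positive")
        if self.window_size % self.step != 0:
            raise ValueError("window_size must be a multiple of step")
        for name, length in self.chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        chrom_col, starts, ends = [], [], []
        self.chrom_slices = {}
        lo = 0
        for name, length in self.chroms.items():
            s = np.arange(0, length, self.step, dtype=np.int64)
            e = np.minimum(s + self.window_size, length)
            chrom_col.extend([name] * len(s))
            starts.append(s)
            ends.append(e)
            self.chrom_slices[name] = slice(lo, lo + len(s))
            lo += len(s)
        self.window_chrom = np.asarray(chrom_col, dtype=object)
        self.window_start = np.concatenate(starts) if starts else np.empty(0, np.int64)
        self.window_end = np.concatenate(ends) if ends else np.empty(0, np.int64)

    @classmethod
    def from_chrom_sizes(
        cls,
        sizes: dict[str, int],
        window_size: int = 800,
        step: int | None = None,
        placed_chroms: list[str] | None = None,
    ) -> "GenomeLayout":
        """Build a layout, optionally restricted to a placed-chromosome whitelist."""
        if placed_chroms is not None:
            sizes = {c: n for c, n in sizes.items() if c in set(placed_chroms)}
        if step is None:
            step = window_size // 2
        return cls(chroms=dict(sizes), window_size=window_size, step=step)

    @property
    def n_windows(self) -> int:
        return len(self.window_start)

    def windows_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of windows intersecting [start, end) on ``chrom``."""
        sl = self.chrom_slices.get(chrom)
        if sl is None:
            return np.empty(0, dtype=np.int64)
        ws = self.window_start[sl]
        we = self.window_end[sl]
        local = np.flatnonzero((ws < end) & (we > start))
        return local + sl.start

    def windows_within(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Windows fully contained in [start, end); falls back to
        overlapping windows when the span contains none (spans are usually
        unions of windows, so containment is the faithful membership)."""
        sl = self.chrom_slices.get(chrom)
        if sl is None:
            return np.empty(0, dtype=np.int64)
        ws = self.window_start[sl]
        we = self.window_end[sl]
        local = np.flatnonzero((ws >= start) & (we <= end))
        if len(local) == 0:
            return self.windows_overlapping(chrom, start, end)
        return local + sl.start


@dataclass
class DepthMatrix:
    """Windows x samples depth, in raw / GC-corrected / normalized layers.

    ``normalized`` is unitless with the diploid baseline pinned to 1.0;
    ``window_mask`` is True for usable windows (calls are only made there).
    """

    layout: GenomeLayout
    samples: list[str]
    raw: np.ndarray
    gc: np.ndarray | None = None
    gc_corrected: np.ndarray | None = None
    normalized: np.ndarray | None = None
    window_mask: np.ndarray | None = None
    dropped_reads: dict[str, int] = field(default_factory=dict)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def to_frame(self, layer: str = "normalized") -> pd.DataFrame:
        arr = getattr(self, layer)
        if arr is None:
            raise ValueError(f"layer {layer!r} not computed")
        df = pd.DataFrame(arr, columns=self.samples)
        df.insert(0, "chrom", self.layout.window_chrom)
        df.insert(1, "start", self.layout.window_start)
        df.insert(2, "end", self.layout.window_end)
        return df


def read_placements_tsv(path) -> pd.DataFrame:
    """Read a per-sample read-placement table (chrom, start, length; 0-based)."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "length"], header=0)
    return df


def compute_window_depth(
    reads: dict[str, pd.DataFrame], layout: GenomeLayout
) -> DepthMatrix:
    """Count reads per window by the read-midpoint rule.

    A read is assigned to every window whose half-open span contains its
    midpoint ``start + length // 2``; with window = 2 x step each read is
    counted in exactly two full windows. Reads on chromosomes absent from
    the layout are dropped (and tallied in ``dropped_reads``).
    """
    samples = list(reads)
    raw = np.zeros((layout.n_windows, len(samples)), dtype=np.float64)
    layers = layout.window_size // layout.step
    dropped: dict[str, int] = {}
    for j, sample in enumerate(samples):
        df = reads[sample]
        if len(df) == 0:
            raise ValueError(f"sample {sample!r} has no reads")
        n_dropped = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            sl = layout.chrom_slices.get(chrom)
            if sl is None:
                n_dropped += len(sub)
                continue
            mid = (
                sub["start"].to_numpy(np.int64)
                + sub["length"].to_numpy(np.int64) // 2
            )
            n_chrom_windows = sl.stop - sl.start
            base = mid // layout.step
            counts = np.zeros(n_chrom_windows, dtype=np.int64)
            for off in range(layers):
                k = base - off
                valid = k >= 0
                counts += np.bincount(k[valid], minlength=n_chrom_windows)[
                    :n_chrom_windows
                ]
            raw[sl, j] += counts
        if n_dropped:
            dropped[sample] = n_dropped
            logger.warning("sample %s: %d reads on non-layout chroms dropped",
                           sample, n_dropped)
    return DepthMatrix(layout=layout, samples=samples, raw=raw, dropped_reads=dropped)


def _lower_median(x: np.ndarray) -> float:
    """Median as an element of x (lower of the central pair for even n)."""
    return float(np.quantile(x, 0.5, method="lower"))


def align_gc_track(gc_track, layout: GenomeLayout) -> np.ndarray:
    """Accept a per-window array or a (chrom, window_start, gc) table."""
    if isinstance(gc_track, pd.DataFrame):
        key = pd.MultiIndex.from_arrays([gc_track["chrom"], gc_track["window_start"]])
        lut = pd.Series(gc_track.iloc[:, -1].to_numpy(), index=key)
        want = pd.MultiIndex.from_arrays([layout.window_chrom, layout.window_start])
        gc = lut.reindex(want).to_numpy(dtype=float)
        if np.isnan(gc).any():
            raise ValueError("gc track does not cover all layout windows")
        return gc
    gc = np.asarray(gc_track, dtype=float)
    if gc.shape != (layout.n_windows,):
        raise ValueError("gc track length does not match layout windows")
    return gc


def gc_normalize(
    matrix: DepthMatrix,
    gc_track,
    n_bins: int = 20,
    min_bin_windows: int = 20,
) -> DepthMatrix:
    """Equalize GC-bin median depth per sample (bin-median rescaling).

    For each sample, windows are binned by GC fraction and counts in bin b
    are multiplied by ``global_median / median(bin b)``. Bins with fewer
    than ``min_bin_windows`` windows, or zero median, are left uncorrected.
    The reference global median is taken over correctable bins only, which
    makes the operation exactly idempotent (lower-median estimator).
    """
    gc = align_gc_track(gc_track, matrix.layout)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    bins = np.clip((gc * n_bins).astype(int), 0, n_bins - 1)
    bin_counts = np.bincount(bins, minlength=n_bins)
    correctable = bin_counts >= min_bin_windows
    in_correctable = correctable[bins]

    corrected = matrix.raw.astype(np.float64).copy()
    for j in range(corrected.shape[1]):
        col = corrected[:, j]
        if not col.any():
            logger.warning("sample %s has all-zero depth; GC correction skipped",
                           matrix.samples[j])
            continue
        if in_correctable.any():
            gmed = _lower_median(col[in_correctable])
        else:
            gmed = _lower_median(col)
        for b in np.flatnonzero(correctable):
            sel = bins == b
            bmed = _lower_median(col[sel])
            if bmed > 0 and gmed > 0:
                col[sel] *= gmed / bmed
    return DepthMatrix(
        layout=matrix.layout,
        samples=matrix.samples,
        raw=matrix.raw,
        gc=gc,
        gc_corrected=corrected,
        dropped_reads=matrix.dropped_reads,
    )


def sample_normalize(
    matrix: DepthMatrix,
    gc_min: float = 0.2,
    gc_max: float = 0.8,
    gc_usability: float = 0.5,
    depth_trim_pct: float = 0.0,
) -> DepthMatrix:
    """Scale each sample so its diploid baseline sits at 1.0, and mask windows.

    A window is usable when (a) its GC fraction lies in [gc_min, gc_max],
    (b) at least ``gc_usability`` of samples have nonzero raw depth there,
    and, optionally, (c) its cross-sample median relative depth is not in
    the extreme ``depth_trim_pct`` percent tails. The trim targets
    systematically aberrant windows of real genomes (collapsed repeats,
    reference errors, where most samples deviate together); it is off by
    default because depth extremes shared by many samples can also be
    bona-fide high-frequency CNVs. Each sample's gc-corrected depth is
    divided by its median over usable windows; the result is
    scale-invariant per sample.
    """
    if matrix.gc_corrected is None:
        raise ValueError("gc_corrected layer missing; run gc_normalize first")
    gc = matrix.gc
    if gc is None:
        raise ValueError("no GC track attached")
    corr = matrix.gc_corrected
    n_windows, n_samples = corr.shape

    mask = (gc >= gc_min) & (gc <= gc_max)
    nonzero_frac = (matrix.raw > 0).mean(axis=1)
    mask &= nonzero_frac >= gc_usability
    # truncated terminal windows have proportionally lower expected depth
    full = (matrix.layout.window_end - matrix.layout.window_start) \
        == matrix.layout.window_size
    if full.any():
        mask &= full
    if not mask.any():
        raise ValueError("all windows masked by GC/usability rules")

    # relative depth (per-sample median-scaled) so the trim is scale-free
    baselines = np.empty(n_samples)
    for j in range(n_samples):
        baselines[j] = np.median(corr[mask, j])
        if baselines[j] <= 0:
            raise ValueError(
                f"sample {matrix.samples[j]!r} has zero median depth; unusable"
            )
    rel = corr / baselines
    if depth_trim_pct > 0:
        med = np.median(rel, axis=1)
        lo = np.percentile(med[mask], depth_trim_pct)
        hi = np.percentile(med[mask], 100 - depth_trim_pct)
        mask &= (med >= lo) & (med <= hi)

    normalized = np.empty_like(corr)
    for j in range(n_samples):
        base = np.median(corr[mask, j])
        if base <= 0:
            raise ValueError(
                f"sample {matrix.samples[j]!r} has zero median depth; unusable"
            )
        normalized[:, j] = corr[:, j] / base
    return DepthMatrix(
        layout=matrix.layout,
        samples=matrix.samples,
        raw=matrix.raw,
        gc=gc,
        gc_corrected=corr,
        normalized=normalized,
        window_mask=mask,
        dropped_reads=matrix.dropped_reads,
    )


def write_depth_tsv(matrix: DepthMatrix, path, layer: str = "normalized") -> None:
    matrix.to_frame(layer).to_csv(path, sep="\t", index=False, float_format="%.6g")
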