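"""Per-sample CNV calling and cross-sample CNVR merging.

Window states follow the read-depth caller convention: normalized depth
below 0.2 is a homozygous deletion, [0.2, 0.7) a heterozygous deletion,
above ``dup_floor`` (default 2 - 0.7 = 1.3, by symmetry) a duplication.
Same-direction runs of windows become per-sample calls; calls from all
samples are agglomerated into CNV regions (CNVRs) when the gap between two
regions is under 20% of their combined length AND the Pearson correlation
of their per-sample depth profiles is significant at the 0.01 level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .depth import DepthMatrix

logger = logging.getLogger(__name__)

MASKED = -1
NEUTRAL = 0
HOM_DEL = 1
HET_DEL = 2
DUP = 3

STATE_NAMES = {HOM_DEL: "hom_del", HET_DEL: "het_del", DUP: "dup"}
DELETION_STATES = frozenset({"hom_del", "het_del"})


@dataclass
class CnvCall:
    """A per-sample CNV segment (union of its member windows)."""

    sample: str
    chrom: str
    start: int
    end: int
    mean_norm_depth: float
    state: str  # hom_del | het_del | dup
    n_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def direction(self) -> int:
        return 1 if self.state == "dup" else -1


@dataclass
class CnvRegion:
    """A merged cross-sample CNV region."""

    id: str
    chrom: str
    start: int
    end: int
    type: str  # deletion | duplication | mixed
    carriers: dict[str, str]  # sample -> state
    copy_number: dict[str, float]  # sample -> 2 x mean normalized depth
    calls: list[CnvCall] = field(default_factory=list, repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def call_window_states(
    matrix: DepthMatrix,
    lower: float = 0.2,
    del_ceiling: float = 0.7,
    dup_floor: float = 1.3,
) -> np.ndarray:
    """Classify every (window, sample) cell into a copy-number state code.

    Boundaries are half-open at the deletion side: nd < lower is hom_del,
    lower <= nd < del_ceiling is het_del, nd > dup_floor is dup. Masked
    windows get the MASKED code and never produce calls.
    """
    if not (0 < lower < del_ceiling < 1 < dup_floor):
        raise ValueError(
            "thresholds must satisfy 0 < lower < del_ceiling < 1 < dup_floor"
        )
    nd = matrix.normalized
    if nd is None:
        raise ValueError("normalized layer missing; run sample_normalize first")
    states = np.full(nd.shape, NEUTRAL, dtype=np.int8)
    states[nd < lower] = HOM_DEL
    states[(nd >= lower) & (nd < del_ceiling)] = HET_DEL
    states[nd > dup_floor] = DUP
    if matrix.window_mask is not None:
        states[~matrix.window_mask, :] = MASKED
    return states


def segment_sample_cnvs(
    states: np.ndarray,
    matrix: DepthMatrix,
    min_windows: int = 2,
    max_gap_windows: int = 1,
    lower: float = 0.2,
) -> list[CnvCall]:
    """Group same-direction non-neutral windows into per-sample calls.

    Deletion states (hom/het) may mix within a run; up to
    ``max_gap_windows`` neutral or masked windows are tolerated inside a
    run; runs with fewer than ``min_windows`` non-neutral windows are
    dropped. Opposite directions never join.
    """
    layout = matrix.layout
    nd = matrix.normalized
    calls: list[CnvCall] = []
    direction = np.zeros(states.shape, dtype=np.int8)
    direction[(states == HOM_DEL) | (states == HET_DEL)] = -1
    direction[states == DUP] = 1

    for j, sample in enumerate(matrix.samples):
        for chrom, sl in layout.chrom_slices.items():
            d = direction[sl, j]
            nz = np.flatnonzero(d)
            if len(nz) == 0:
                continue
            run: list[int] = [nz[0]]
            for idx in nz[1:]:
                prev = run[-1]
                gap = idx - prev - 1
                if d[idx] == d[prev] and gap <= max_gap_windows:
                    run.append(idx)
                else:
                    calls.extend(
                        _finish_run(run, d, nd, j, sl, chrom, sample, layout,
                                    min_windows, lower)
                    )
                    run = [idx]
            calls.extend(
                _finish_run(run, d, nd, j, sl, chrom, sample, layout,
                            min_windows, lower)
            )
    return calls


def _finish_run(run, d, nd, col, sl, chrom, sample, layout, min_windows, lower):
    if len(run) < min_windows:
        return []
    members = np.asarray(run) + sl.start
    mean_depth = float(np.mean(nd[members, col]))
    start = int(layout.window_start[members[0]])
    end = int(layout.window_end[members[-1]])
    if d[run[0]] > 0:
        state = "dup"
    else:
        state = "hom_del" if mean_depth < lower else "het_del"
    return [
        CnvCall(
            sample=sample,
            chrom=chrom,
            start=start,
            end=end,
            mean_norm_depth=mean_depth,
            state=state,
            n_windows=len(run),
        )
    ]


def region_depth_vector(
    matrix: DepthMatrix, chrom: str, start: int, end: int
) -> np.ndarray | None:
    """Per-sample mean normalized depth over the unmasked windows of a span."""
    idx = matrix.layout.windows_within(chrom, start, end)
    if matrix.window_mask is not None:
        idx = idx[matrix.window_mask[idx]]
    if len(idx) == 0:
        return None
    return matrix.normalized[idx, :].mean(axis=0)


def _corr_significant(v1: np.ndarray, v2: np.ndarray, alpha: float) -> bool:
    if v1 is None or v2 is None:
        return False
    if np.std(v1) == 0 or np.std(v2) == 0:
        return False
    r, p = stats.pearsonr(v1, v2)
    return bool(p < alpha)


@dataclass
class _Proto:
    chrom: str
    start: int
    end: int
    calls: list[CnvCall]


def merge_to_cnvrs(
    calls: list[CnvCall],
    matrix: DepthMatrix,
    merge_gap_fraction: float = 0.2,
    corr_alpha: float = 0.01,
) -> list[CnvRegion]:
    """Agglomerate per-sample calls into CNVRs.

    Two neighbouring candidate regions merge when the gap between them is
    less than ``merge_gap_fraction`` times their combined length (overlap
    counts as gap <= 0) and the per-sample depth profiles of the two spans
    are positively-testing under an exact two-sided Pearson test at
    ``corr_alpha``. Merging sweeps left-to-right and repeats until a fixed
    point. With fewer than 4 samples the correlation is untestable and the
    gap rule alone applies (warned).
    """
    if not calls:
        return []
    n_samples = len(matrix.samples)
    corr_testable = n_samples >= 4
    if not corr_testable:
        logger.warning(
            "fewer than 4 samples: merging on the gap rule only "
            "(correlation untestable)"
        )

    by_chrom: dict[str, list[_Proto]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(
            _Proto(chrom=c.chrom, start=c.start, end=c.end, calls=[c])
        )

    regions: list[CnvRegion] = []
    counter = 0
    for chrom in matrix.layout.chroms:
        protos = by_chrom.get(chrom)
        if not protos:
            continue
        protos.sort(key=lambda r: (r.start, r.end))
        changed = True
        while changed:
            changed = False
            i = 0
            while i < len(protos) - 1:
                a, b = protos[i], protos[i + 1]
                if _should_merge(a, b, matrix, merge_gap_fraction,
                                 corr_alpha, corr_testable):
                    a.end = max(a.end, b.end)
                    a.calls.extend(b.calls)
                    del protos[i + 1]
                    changed = True
                else:
                    i += 1
        for p in protos:
            counter += 1
            regions.append(_build_region(p, matrix, f"cnvr_{counter}"))
    return regions


def _should_merge(a: _Proto, b: _Proto, matrix, gap_frac, alpha, testable) -> bool:
    gap = b.start - a.end
    if gap >= gap_frac * ((a.end - a.start) + (b.end - b.start)):
        return False
    if a.start == b.start and a.end == b.end:
        return True  # identical spans are the same locus by construction
    if not testable:
        return True
    v1 = region_depth_vector(matrix, a.chrom, a.start, a.end)
    v2 = region_depth_vector(matrix, b.chrom, b.start, b.end)
    return _corr_significant(v1, v2, alpha)


def _build_region(p: _Proto, matrix: DepthMatrix, region_id: str) -> CnvRegion:
    carriers: dict[str, str] = {}
    best: dict[str, CnvCall] = {}
    for c in p.calls:
        cur = best.get(c.sample)
        if cur is None or c.n_windows > cur.n_windows:
            best[c.sample] = c
    for sample, c in best.items():
        carriers[sample] = c.state
    vec = region_depth_vector(matrix, p.chrom, p.start, p.end)
    if vec is None:
        cn = {s: float("nan") for s in matrix.samples}
    else:
        cn = {s: float(2.0 * v) for s, v in zip(matrix.samples, vec)}
    region = CnvRegion(
        id=region_id,
        chrom=p.chrom,
        start=p.start,
        end=p.end,
        type="",
        carriers=carriers,
        copy_number=cn,
        calls=list(p.calls),
    )
    region.type = classify_cnvr_type(region)
    return region


def classify_cnvr_type(region: CnvRegion) -> str:
    """deletion if all carrier states are deletions, duplication if all
    duplications, mixed when both occur."""
    if not region.carriers:
        raise ValueError(f"region {region.id} has no carriers")
    states = set(region.carriers.values())
    bad = states - (DELETION_STATES | {"dup"})
    if bad:
        raise ValueError(f"region {region.id}: non-CNV carrier state {bad}")
    has_del = bool(states & DELETION_STATES)
    has_dup = "dup" in states
    if has_del and has_dup:
        return "mixed"
    return "deletion" if has_del else "duplication"


def filter_cnvrs(
    regions: list[CnvRegion],
    min_samples: int = 2,
    placed_chroms: list[str] | None = None,
) -> list[CnvRegion]:
    """Keep CNVRs carried by >= min_samples samples on placed chromosomes."""
    placed = set(placed_chroms) if placed_chroms is not None else None
    out = []
    for r in regions:
        if r.n_carriers < min_samples:
            continue
        if placed is not None and r.chrom not in placed:
            continue
        out.append(r)
    return out


def regions_to_frame(regions: list[CnvRegion]):
    """BED-like table of CNVRs (0-based half-open coordinates)."""
    import json

    import pandas as pd

    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "id": r.id,
                "type": r.type,
                "n_carriers": r.n_carriers,
                "carriers": ",".join(f"{s}:{st}" for s, st in sorted(r.carriers.items())),
                "copy_number": json.dumps(
                    {s: round(v, 4) for s, v in sorted(r.copy_number.items())}
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "id", "type", "n_carriers",
                 "carriers", "copy_number"],
    )
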