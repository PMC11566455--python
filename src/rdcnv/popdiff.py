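"""V_ST population differentiation on CNVR copy numbers.

V_ST = (V_T - V_S) / V_T, where V_T is the variance of copy numbers pooled
over the two groups and V_S the population-size-weighted mean of the
within-group variances (Redon-style, analogous to F_ST). V_ST is 1 for a
fixed difference, ~0 for no between-group structure, and may be slightly
negative by sampling; it is undefined when V_T = 0 (copy number invariant).

Variances are population variances (ddof=0) by default; the sample
(ddof=1) form is available since conventions differ between tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CnvRegion
from .depth import DepthMatrix


@dataclass
class VstRecord:
    cnvr_id: str
    chrom: str
    midpoint: int
    v_t: float
    v_s: float
    v_st: float  # nan when undefined (v_t == 0)
    group_sizes: tuple[int, int]

    @property
    def defined(self) -> bool:
        return np.isfinite(self.v_st)


def copy_number_vector(region: CnvRegion, matrix: DepthMatrix) -> np.ndarray:
    """Continuous per-sample copy number: 2 x mean normalized depth over
    the region's unmasked member windows (windows fully inside the span)."""
    idx = matrix.layout.windows_within(region.chrom, region.start, region.end)
    if matrix.window_mask is not None:
        idx = idx[matrix.window_mask[idx]]
    if len(idx) == 0:
        raise ValueError(f"region {region.id}: all windows masked")
    return 2.0 * matrix.normalized[idx, :].mean(axis=0)


def compute_vst(
    cn_values: np.ndarray,
    group_labels,
    cnvr_id: str = "",
    chrom: str = "",
    midpoint: int = 0,
    ddof: int = 0,
) -> VstRecord:
    """V_ST of one CNVR between the two groups in ``group_labels``."""
    cn = np.asarray(cn_values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    masks = [labels == g for g in groups]
    sizes = [int(m.sum()) for m in masks]
    for g, n in zip(groups, sizes):
        if n < 2:
            raise ValueError(f"group {g!r} has {n} sample(s); need >= 2")
    n1, n2 = sizes
    v_t = float(np.var(cn, ddof=ddof))
    v1 = float(np.var(cn[masks[0]], ddof=ddof))
    v2 = float(np.var(cn[masks[1]], ddof=ddof))
    v_s = (n1 * v1 + n2 * v2) / (n1 + n2)
    v_st = (v_t - v_s) / v_t if v_t > 0 else float("nan")
    return VstRecord(
        cnvr_id=cnvr_id,
        chrom=chrom,
        midpoint=midpoint,
        v_t=v_t,
        v_s=v_s,
        v_st=v_st,
        group_sizes=(n1, n2),
    )


def vst_scan(
    regions: list[CnvRegion],
    matrix: DepthMatrix,
    sample_to_pop: dict[str, str],
    focal_pop: str,
    ddof: int = 0,
) -> list[VstRecord]:
    """Per-CNVR V_ST of the focal population against all others pooled."""
    labels = np.array(
        ["focal" if sample_to_pop[s] == focal_pop else "rest" for s in matrix.samples]
    )
    records = []
    for r in regions:
        cn = copy_number_vector(r, matrix)
        records.append(
            compute_vst(
                cn,
                labels,
                cnvr_id=r.id,
                chrom=r.chrom,
                midpoint=(r.start + r.end) // 2,
                ddof=ddof,
            )
        )
    return records


def select_top_fraction(
    records: list[VstRecord], fraction: float = 0.05
) -> tuple[list[VstRecord], float]:
    """Records in the top ``fraction`` of defined V_ST values (ties included).

    Undefined records (V_T = 0) carry no differentiation signal and are
    excluded from the quantile. Returns (selected, threshold).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    defined = [r for r in records if r.defined]
    if not defined:
        raise ValueError("no defined V_ST records to rank")
    values = np.array([r.v_st for r in defined])
    threshold = float(np.quantile(values, 1.0 - fraction))
    selected = [r for r in defined if r.v_st >= threshold]
    return selected, threshold


def vst_table(records: list[VstRecord], threshold: float | None = None) -> pd.DataFrame:
    """Manhattan-ready table (chrom, position, v_st, above_threshold)."""
    df = pd.DataFrame(
        {
            "cnvr_id": [r.cnvr_id for r in records],
            "chrom": [r.chrom for r in records],
            "midpoint": [r.midpoint for r in records],
            "v_t": [r.v_t for r in records],
            "v_s": [r.v_s for r in records],
            "v_st": [r.v_st for r in records],
            "flag": ["ok" if r.defined else "undefined" for r in records],
        }
    )
    if threshold is not None:
        df["above_threshold"] = (df["v_st"] >= threshold) & (df["flag"] == "ok")
    return df
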