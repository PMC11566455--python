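"""CNVR annotation: genic context, size/breed distributions, QTL overlap.

All coordinates are 0-based half-open; two intervals overlap when their
intersection is at least ``min_overlap_bp`` (default 1 bp). A CNVR gets a
single genic label with precedence exonic > intronic > intergenic, the
three-class scheme of ANNOVAR-style region annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

QTL_CATEGORIES = (
    "reproduction",
    "production",
    "meat_carcass",
    "milk",
    "exterior",
    "health",
)


def pct(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage 100*count/total rounded half-up to ``ndigits`` decimals."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty span")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        merged: list[tuple[int, int]] = []
        for s, e in exons:
            if s < self.start or e > self.end or e <= s:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside span")
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.exons = merged


@dataclass
class QtlRecord:
    qtl_id: str
    chrom: str
    start: int
    end: int
    category: str
    trait_name: str = ""

    def __post_init__(self) -> None:
        if self.category not in QTL_CATEGORIES:
            raise ValueError(
                f"QTL {self.qtl_id}: unknown category {self.category!r}"
            )


class IntervalSet:
    """Sorted-interval index per chromosome with O(log n) existence queries."""

    def __init__(self, intervals: list[tuple[str, int, int, object]]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        self._raw_ends: dict[str, np.ndarray] = {}
        grouped: dict[str, list] = {}
        for chrom, start, end, payload in intervals:
            if end <= start:
                raise ValueError(f"malformed interval {payload!r}: [{start},{end})")
            grouped.setdefault(chrom, []).append((start, end, payload))
        for chrom, rows in grouped.items():
            rows.sort(key=lambda r: (r[0], r[1]))
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            payloads = [r[2] for r in rows]
            self._by_chrom[chrom] = (starts, np.maximum.accumulate(ends), payloads)
            self._raw_ends[chrom] = ends

    def overlaps_any(self, chrom: str, qs: int, qe: int, min_bp: int = 1) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, prefix_max_end, _ = entry
        hi = int(np.searchsorted(starts, qe - min_bp, side="right"))
        if hi == 0:
            return False
        return bool(prefix_max_end[hi - 1] >= qs + min_bp)

    def overlapping(self, chrom: str, qs: int, qe: int, min_bp: int = 1) -> list:
        entry = self._by_chrom.get(chrom)
        if entry is None or qe - qs < min_bp:
            return []
        starts, _, payloads = entry
        ends = self._raw_ends[chrom]
        hi = int(np.searchsorted(starts, qe - min_bp, side="right"))
        sel = np.flatnonzero(
            (ends[:hi] >= qs + min_bp) & (ends[:hi] - starts[:hi] >= min_bp)
        )
        return [payloads[i] for i in sel]


def genic_context(regions, genes: list[GeneModel]) -> list[str]:
    """Label each CNVR exonic / intronic / intergenic (precedence in that order)."""
    exon_idx = IntervalSet(
        [(g.chrom, s, e, g.gene_id) for g in genes for s, e in g.exons]
    )
    gene_idx = IntervalSet([(g.chrom, g.start, g.end, g.gene_id) for g in genes])
    labels = []
    for r in regions:
        if r.end <= r.start:
            raise ValueError(f"malformed region {r.id}: [{r.start},{r.end})")
        if exon_idx.overlaps_any(r.chrom, r.start, r.end):
            labels.append("exonic")
        elif gene_idx.overlaps_any(r.chrom, r.start, r.end):
            labels.append("intronic")
        else:
            labels.append("intergenic")
    return labels


SIZE_BIN_EDGES_KB = (1.0, 2.0, 5.0, 10.0)


def size_distribution(regions, bin_edges_kb=SIZE_BIN_EDGES_KB) -> pd.DataFrame:
    """Half-open size bins in kb, with an explicit '<min' overflow bin.

    Returns a table with columns bin / count / pct. Percentages of an empty
    input are reported as 0 with the ``empty`` flag in the attrs.
    """
    edges = list(bin_edges_kb)
    names = [f"<{edges[0]:g} kb"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        names.append(f"{lo:g}-{hi:g} kb")
    names.append(f">{edges[-1]:g} kb")
    counts = dict.fromkeys(names, 0)
    for r in regions:
        kb = r.length / 1000.0
        if kb < edges[0]:
            counts[names[0]] += 1
        elif kb >= edges[-1]:
            counts[names[-1]] += 1
        else:
            for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
                if lo <= kb < hi:
                    counts[names[i + 1]] += 1
                    break
    total = sum(counts.values())
    df = pd.DataFrame(
        {"bin": names, "count": [counts[n] for n in names]}
    )
    df["pct"] = [pct(c, total) for c in df["count"]]
    df.attrs["empty"] = total == 0
    return df


def breed_sharing(regions, sample_to_pop: dict[str, str]) -> dict:
    """Population membership of each CNVR and the full Venn-cell breakdown.

    A CNVR belongs to population P when at least one carrier is from P;
    unique-to-P means it belongs to P and to no other population. The
    2^k - 1 Venn cells partition the CNVR set.
    """
    pops = sorted(set(sample_to_pop.values()))
    cells: dict[frozenset, int] = {}
    unique = dict.fromkeys(pops, 0)
    membership = {}
    for r in regions:
        r_pops = set()
        for s in r.carriers:
            if s not in sample_to_pop:
                raise ValueError(f"carrier sample {s!r} not in the population map")
            r_pops.add(sample_to_pop[s])
        key = frozenset(r_pops)
        cells[key] = cells.get(key, 0) + 1
        membership[r.id] = sorted(r_pops)
        if len(r_pops) == 1:
            unique[next(iter(r_pops))] += 1
    return {
        "populations": pops,
        "venn_cells": {"+".join(sorted(k)): v for k, v in cells.items()},
        "unique": unique,
        "membership": membership,
        "total": len(list(regions)),
    }


def qtl_overlap(regions, qtls: list[QtlRecord], min_overlap_bp: int = 1) -> dict:
    """Overlap CNVRs with QTL intervals; summarize per trait category.

    Reports the number and percentage of CNVRs hitting >= 1 QTL, the count
    of distinct QTLs hit, and each category's share of those QTLs (one QTL
    belongs to one category, but one CNVR may hit many QTLs).
    """
    idx = IntervalSet([(q.chrom, q.start, q.end, q) for q in qtls])
    regions = list(regions)
    hits_per_region: dict[str, list[str]] = {}
    qtls_hit: dict[str, QtlRecord] = {}
    n_overlapping = 0
    for r in regions:
        found = idx.overlapping(r.chrom, r.start, r.end, min_bp=min_overlap_bp)
        if found:
            n_overlapping += 1
            hits_per_region[r.id] = [q.qtl_id for q in found]
            for q in found:
                qtls_hit[q.qtl_id] = q
    n_total = len(regions)
    n_qtls = len(qtls_hit)
    per_category = {
        cat: sum(1 for q in qtls_hit.values() if q.category == cat)
        for cat in QTL_CATEGORIES
    }
    return {
        "n_cnvrs_total": n_total,
        "n_overlapping": n_overlapping,
        "pct_overlapping": pct(n_overlapping, n_total),
        "n_qtls_hit": n_qtls,
        "per_category_counts": per_category,
        "per_category_pct": {c: pct(n, n_qtls) for c, n in per_category.items()},
        "hits_per_region": hits_per_region,
    }


def compare_cnvr_sets(set_a, set_b, min_overlap_bp: int = 1,
                      reciprocal: float | None = None) -> tuple[int, float]:
    """Count regions of set_a overlapping set_b; return (n, ratio %).

    ``reciprocal`` optionally requires the intersection to cover that
    fraction of both intervals (cross-study comparisons).
    """
    set_a = list(set_a)
    set_b = list(set_b)
    if not set_a:
        raise ValueError("set_a is empty: overlap ratio undefined")
    idx = IntervalSet([(r.chrom, r.start, r.end, r) for r in set_b])
    n = 0
    for a in set_a:
        found = idx.overlapping(a.chrom, a.start, a.end, min_bp=min_overlap_bp)
        if reciprocal is not None:
            ok = False
            for b in found:
                inter = min(a.end, b.end) - max(a.start, b.start)
                if (inter >= reciprocal * (a.end - a.start)
                        and inter >= reciprocal * (b.end - b.start)):
                    ok = True
                    break
            if ok:
                n += 1
        elif found:
            n += 1
    return n, pct(n, len(set_a))


def read_genes_bed(path) -> list[GeneModel]:
    """BED12-subset reader: chrom start end name score strand ... blocks."""
    genes = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for _, row in df.iterrows():
        chrom, start, end, name = row[0], int(row[1]), int(row[2]), str(row[3])
        if len(row) >= 12:
            sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
            offs = [int(x) for x in str(row[11]).rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
        else:
            exons = [(start, end)]
        genes.append(GeneModel(gene_id=name, chrom=str(chrom), start=start,
                               end=end, exons=exons))
    return genes


def read_qtls_bed(path) -> list[QtlRecord]:
    """BED + category (+ optional trait name) reader."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(
            QtlRecord(
                qtl_id=str(row[3]),
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                category=str(row[4]),
                trait_name=str(row[5]) if len(row) > 5 else "",
            )
        )
    return out
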