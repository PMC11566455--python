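"""End-to-end orchestration: depth -> calls -> CNVRs -> annotation -> V_ST.

``run_from_cohort`` executes every stage in memory on a (simulated or
loaded) cohort and returns all intermediate objects; ``run_pipeline``
wraps it with config handling, output writing and a provenance manifest.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import calling, depth, popdiff, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, serializable to YAML."""

    # input paths (real-data mode); ignored when simulate=True
    reads_dir: str | None = None
    gc_track: str | None = None
    chrom_sizes: str | None = None
    genes: str | None = None
    qtls: str | None = None
    sample_map: str | None = None
    outdir: str = "results/pipeline"
    # simulation mode
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    n_genes: int = 120
    n_qtls: int = 60
    # windowing / normalization
    window_size: int = 800
    step: int = 400
    gc_bins: int = 20
    min_bin_windows: int = 20
    gc_min: float = 0.2
    gc_max: float = 0.8
    gc_usability: float = 0.5
    depth_trim_pct: float = 0.0
    # calling thresholds
    lower: float = 0.2
    del_ceiling: float = 0.7
    dup_floor: float = 1.3
    min_windows: int = 2
    max_gap_windows: int = 1
    # merging / filtering
    merge_gap_fraction: float = 0.2
    corr_alpha: float = 0.01
    min_samples: int = 2
    placed_chroms: list[str] | None = None
    # differentiation scan
    vst_top_fraction: float = 0.05
    focal_pop: str | None = None
    # misc
    size_bin_edges_kb: tuple = ann.SIZE_BIN_EDGES_KB
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_bin_edges_kb"] = list(d["size_bin_edges_kb"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "size_bin_edges_kb" in d:
            d["size_bin_edges_kb"] = tuple(d["size_bin_edges_kb"])
        return cls(**d)


@dataclass
class PipelineResult:
    cohort: "simulate.Cohort | None"
    matrix: depth.DepthMatrix
    calls: list
    regions: list
    genic_labels: list[str]
    size_table: pd.DataFrame
    sharing: dict
    qtl_summary: dict
    vst_records: list
    vst_selected: list
    vst_threshold: float
    recovery: dict | None


def stage_depth(cohort, cfg: PipelineConfig) -> depth.DepthMatrix:
    matrix = depth.compute_window_depth(cohort.reads, cohort.layout)
    matrix = depth.gc_normalize(matrix, cohort.gc_track, n_bins=cfg.gc_bins,
                                min_bin_windows=cfg.min_bin_windows)
    return depth.sample_normalize(
        matrix, gc_min=cfg.gc_min, gc_max=cfg.gc_max,
        gc_usability=cfg.gc_usability, depth_trim_pct=cfg.depth_trim_pct,
    )


def stage_call(matrix: depth.DepthMatrix, cfg: PipelineConfig):
    states = calling.call_window_states(
        matrix, lower=cfg.lower, del_ceiling=cfg.del_ceiling,
        dup_floor=cfg.dup_floor,
    )
    calls = calling.segment_sample_cnvs(
        states, matrix, min_windows=cfg.min_windows,
        max_gap_windows=cfg.max_gap_windows, lower=cfg.lower,
    )
    regions = calling.merge_to_cnvrs(
        calls, matrix, merge_gap_fraction=cfg.merge_gap_fraction,
        corr_alpha=cfg.corr_alpha,
    )
    regions = calling.filter_cnvrs(
        regions, min_samples=cfg.min_samples, placed_chroms=cfg.placed_chroms,
    )
    return calls, regions


def run_from_cohort(
    cohort,
    cfg: PipelineConfig,
    genes=None,
    qtls=None,
) -> PipelineResult:
    """All pipeline stages on an in-memory cohort."""
    t0 = time.time()
    matrix = stage_depth(cohort, cfg)
    logger.info("depth stage: %d windows x %d samples (%.1fs)",
                matrix.layout.n_windows, len(matrix.samples), time.time() - t0)
    calls, regions = stage_call(matrix, cfg)
    logger.info("calling stage: %d per-sample calls -> %d CNVRs",
                len(calls), len(regions))

    if genes is None or qtls is None:
        g, q = simulate.simulate_annotations(
            cohort.layout, cfg.n_genes, cfg.n_qtls, seed=cfg.seed + 1
        )
        genes = genes if genes is not None else g
        qtls = qtls if qtls is not None else q
    genic = ann.genic_context(regions, genes)
    size_table = ann.size_distribution(regions, bin_edges_kb=cfg.size_bin_edges_kb)
    sharing = ann.breed_sharing(regions, cohort.sample_to_pop)
    qtl_summary = ann.qtl_overlap(regions, qtls)

    focal = cfg.focal_pop
    if focal is None:
        pops = sorted(set(cohort.sample_to_pop.values()))
        focal = pops[-1]
    vst_records = popdiff.vst_scan(regions, matrix, cohort.sample_to_pop, focal)
    defined = [r for r in vst_records if r.defined]
    if defined:
        vst_selected, vst_threshold = popdiff.select_top_fraction(
            vst_records, fraction=cfg.vst_top_fraction
        )
    else:
        vst_selected, vst_threshold = [], float("nan")

    recovery = None
    if getattr(cohort, "truth", None):
        recovery = simulate.evaluate_recovery(
            cohort.truth, regions, cohort.layout, min_carriers=cfg.min_samples
        )
        logger.info("recovery vs truth: recall=%.3f precision=%.3f",
                    recovery["recall"], recovery["precision"])
    return PipelineResult(
        cohort=cohort,
        matrix=matrix,
        calls=calls,
        regions=regions,
        genic_labels=genic,
        size_table=size_table,
        sharing=sharing,
        qtl_summary=qtl_summary,
        vst_records=vst_records,
        vst_selected=vst_selected,
        vst_threshold=vst_threshold,
        recovery=recovery,
    )


def population_summary(result: PipelineResult) -> pd.DataFrame:
    """Per-breed CNVR summary (count, length, unique, type breakdown,
    % of genome) plus a merged row."""
    regions = result.regions
    s2p = result.cohort.sample_to_pop
    genome_bp = sum(result.matrix.layout.chroms.values())
    pops = sorted(set(s2p.values()))
    rows = []
    for pop in pops + ["merged"]:
        if pop == "merged":
            sel = regions
            n_unique = 0
        else:
            sel = [r for r in regions if any(s2p[s] == pop for s in r.carriers)]
            n_unique = sum(
                1
                for r in sel
                if {s2p[s] for s in r.carriers} == {pop}
            )
        n_dup = sum(1 for r in sel if r.type == "duplication")
        n_del = sum(1 for r in sel if r.type == "deletion")
        n_mix = sum(1 for r in sel if r.type == "mixed")
        total_len = sum(r.length for r in sel)
        rows.append(
            {
                "population": pop,
                "n_samples": (len(s2p) if pop == "merged"
                              else sum(1 for p in s2p.values() if p == pop)),
                "cnvrs": len(sel),
                "length_bp": total_len,
                "unique": n_unique,
                "dup": n_dup,
                "del": n_del,
                "both": n_mix,
                "pct_genome": ann.pct(total_len, genome_bp),
            }
        )
    return pd.DataFrame(rows)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_cohort_from_paths(cfg: PipelineConfig):
    """Real-data mode: assemble a cohort from TSV inputs."""
    sizes = pd.read_csv(cfg.chrom_sizes, sep="\t", header=None,
                        names=["chrom", "length"])
    layout = depth.GenomeLayout.from_chrom_sizes(
        dict(zip(sizes["chrom"], sizes["length"])),
        window_size=cfg.window_size, step=cfg.step,
        placed_chroms=cfg.placed_chroms,
    )
    reads = {}
    for fn in sorted(os.listdir(cfg.reads_dir)):
        if fn.startswith("reads_") and fn.endswith(".tsv"):
            sample = fn[len("reads_"):-len(".tsv")]
            reads[sample] = depth.read_placements_tsv(os.path.join(cfg.reads_dir, fn))
    gc_df = pd.read_csv(cfg.gc_track, sep="\t")
    gc = depth.align_gc_track(gc_df, layout)
    smap = pd.read_csv(cfg.sample_map, sep="\t")
    sample_to_pop = dict(zip(smap["sample"], smap["population"]))
    return simulate.Cohort(
        config=None, layout=layout, reads=reads, gc_track=gc,
        truth=[], sample_to_pop=sample_to_pop,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run all stages and write the report bundle under ``cfg.outdir``."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {"parameters": cfg.as_dict(), "seed": cfg.seed,
                      "inputs": {}, "stages": []}
    genes = qtls = None
    try:
        if cfg.simulate:
            sim_cfg = simulate.SimConfig(seed=cfg.seed, window_size=cfg.window_size,
                                         step=cfg.step, **cfg.sim)
            cohort = simulate.simulate_cohort(sim_cfg)
            manifest["stages"].append("simulate")
        else:
            for key in ("gc_track", "chrom_sizes", "sample_map"):
                p = getattr(cfg, key)
                if p is None or not os.path.exists(p):
                    raise FileNotFoundError(f"input path {key!r} missing: {p}")
                manifest["inputs"][key] = _sha256(p)
            cohort = load_cohort_from_paths(cfg)
            if cfg.genes:
                genes = ann.read_genes_bed(cfg.genes)
            if cfg.qtls:
                qtls = ann.read_qtls_bed(cfg.qtls)
        result = run_from_cohort(cohort, cfg, genes=genes, qtls=qtls)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        manifest["error"] = str(exc)
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    write_report(result, cfg)
    manifest["stages"] += ["depth", "call", "merge", "filter",
                           "annotate", "vst", "report"]
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return result


def write_report(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = cfg.outdir
    os.makedirs(out, exist_ok=True)
    cnvr_df = calling.regions_to_frame(result.regions)
    cnvr_df["genic_context"] = result.genic_labels
    cnvr_df.to_csv(os.path.join(out, "cnvrs.tsv"), sep="\t", index=False)

    population_summary(result).to_csv(
        os.path.join(out, "summary_by_population.tsv"), sep="\t", index=False
    )
    result.size_table.to_csv(
        os.path.join(out, "size_distribution.tsv"), sep="\t", index=False
    )
    genic_counts = pd.Series(result.genic_labels).value_counts()
    total = int(genic_counts.sum())
    pd.DataFrame(
        {
            "context": ["exonic", "intronic", "intergenic"],
            "count": [int(genic_counts.get(c, 0))
                      for c in ("exonic", "intronic", "intergenic")],
            "pct": [ann.pct(int(genic_counts.get(c, 0)), total)
                    for c in ("exonic", "intronic", "intergenic")],
        }
    ).to_csv(os.path.join(out, "genic_context.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "breed_sharing.json"), "w") as fh:
        json.dump({k: v for k, v in result.sharing.items() if k != "membership"},
                  fh, indent=1, sort_keys=True)
    with open(os.path.join(out, "qtl_overlap.json"), "w") as fh:
        json.dump({k: v for k, v in result.qtl_summary.items()
                   if k != "hits_per_region"}, fh, indent=1, sort_keys=True)
    popdiff.vst_table(result.vst_records, result.vst_threshold).to_csv(
        os.path.join(out, "vst.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    if result.recovery is not None:
        rec = {k: v for k, v in result.recovery.items() if k != "matches"}
        with open(os.path.join(out, "recovery.json"), "w") as fh:
            json.dump(rec, fh, indent=1, sort_keys=True)
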