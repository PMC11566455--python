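"""Synthetic WGS cohort generator with planted CNVs.

Emulates the statistical structure a read-depth CNV caller relies on: a
multi-chromosome toy genome with a smooth GC track, three populations of
samples sequenced to ~15X with Poisson window counts, a unimodal
multiplicative GC-depth bias peaking at GC = 0.5, per-sample log-normal
library-scale factors, and planted deletions (het/hom) and duplications
whose carrier frequencies are population-stratified. A subset of events is
strongly differentiated in the focal population so a V_ST scan has signal
to recover.

Reads are uniform-start fixed-length placements; per fine-bin (one window
step) counts are Poisson with rate

    mean_depth * step / read_length * (CN / 2) * gc_bias(GC) * sample_scale

which makes read-depth calling exact in expectation. Events are planted on
the step grid with generous spacing so each truth event is a distinct
locus. ``depth_noise="none"`` replaces Poisson draws with their rounded
expectations for exact zero-noise tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth import GenomeLayout
from .annotate import GeneModel, QtlRecord, QTL_CATEGORIES


@dataclass
class SimConfig:
    n_chroms: int = 5
    chrom_length: int = 1_000_000
    window_size: int = 800
    step: int = 400
    window_gc_profile: np.ndarray | None = None  # per fine bin, optional
    n_populations: int = 3
    samples_per_pop: int = 10
    mean_depth: float = 15.0
    read_length: int = 100
    gc_bias_strength: float = 0.3
    n_cnvs: int = 60
    cnv_length_range: tuple[int, int] = (3200, 16000)
    del_fraction: float = 0.55
    het_fraction: float = 0.8  # het vs hom among deletion carriers
    dup_cn3_fraction: float = 0.8  # CN=3 vs CN=4 among duplication carriers
    n_differentiated: int = 3
    differentiated_focal_freq: float = 0.9
    differentiated_other_freq: float = 0.02
    pop_freq_spec: list[dict[str, float]] | None = None  # per event, pop -> freq
    scale_sd: float = 0.1  # log-normal sd of per-sample library scale
    depth_noise: str = "poisson"  # or "none"
    pop_names: tuple[str, ...] | None = None
    focal_pop_index: int = -1  # the differentiated (high-altitude-like) pop
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "window_size", "step",
                     "n_populations", "samples_per_pop", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        if self.mean_depth <= 0:
            raise ValueError("SimConfig.mean_depth must be positive")
        if self.window_size % self.step != 0:
            raise ValueError("SimConfig.window_size must be a multiple of step")
        if self.read_length > self.step:
            raise ValueError("SimConfig.read_length must not exceed step")
        lo, hi = self.cnv_length_range
        if lo < self.window_size:
            raise ValueError(
                "SimConfig.cnv_length_range minimum must be >= window_size"
            )
        if hi < lo:
            raise ValueError("SimConfig.cnv_length_range must be (lo, hi) with lo <= hi")
        for name in ("del_fraction", "het_fraction", "dup_cn3_fraction",
                     "differentiated_focal_freq", "differentiated_other_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"SimConfig.{name} must lie in [0, 1]")
        if self.pop_freq_spec is not None:
            for i, spec in enumerate(self.pop_freq_spec):
                for pop, f in spec.items():
                    if not 0 <= f <= 1:
                        raise ValueError(
                            f"SimConfig.pop_freq_spec[{i}][{pop!r}] must lie in [0, 1]"
                        )
        if self.depth_noise not in ("poisson", "none"):
            raise ValueError("SimConfig.depth_noise must be 'poisson' or 'none'")
        if self.pop_names is None:
            self.pop_names = tuple(f"pop{i + 1}" for i in range(self.n_populations))
        if len(self.pop_names) != self.n_populations:
            raise ValueError("SimConfig.pop_names length must equal n_populations")

    @property
    def focal_pop(self) -> str:
        return self.pop_names[self.focal_pop_index]

    @property
    def bins_per_chrom(self) -> int:
        return math.ceil(self.chrom_length / self.step)


@dataclass
class TruthCnv:
    """A planted CNV event (0-based half-open, aligned to the step grid)."""

    id: str
    chrom: str
    start: int
    end: int
    kind: str  # deletion | duplication
    copy_number_by_sample: dict[str, int]  # carriers only; others are CN=2
    population_frequencies: dict[str, float]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_carriers(self) -> int:
        return len(self.copy_number_by_sample)


@dataclass
class Cohort:
    config: SimConfig
    layout: GenomeLayout
    reads: dict[str, pd.DataFrame]  # sample -> (chrom, start, length)
    gc_track: np.ndarray  # per layout window
    truth: list[TruthCnv]
    sample_to_pop: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return list(self.reads)


def gc_bias_factor(gc: np.ndarray, strength: float) -> np.ndarray:
    """Unimodal multiplicative depth bias, peaking at GC = 0.5."""
    return np.exp(-strength * ((np.asarray(gc) - 0.5) / 0.5) ** 2)


def _default_gc_profile(n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth GC landscape in ~[0.3, 0.65] (long-period isochore-like waves)."""
    i = np.arange(n_bins)
    gc = (
        0.45
        + 0.10 * np.sin(2 * np.pi * i / 400)
        + 0.05 * np.sin(2 * np.pi * i / 97 + rng.uniform(0, 2 * np.pi))
    )
    gc += rng.normal(0, 0.01, size=n_bins)
    # smooth local noise so adjacent bins stay similar
    kernel = np.ones(5) / 5
    gc = np.convolve(gc, kernel, mode="same")
    return np.clip(gc, 0.25, 0.70)


def _plant_events(config: SimConfig, rng: np.random.Generator,
                  chrom_names: list[str]) -> list[dict]:
    """Choose event intervals on the step grid, well separated.

    Neighbouring events keep a gap of at least two windows plus a quarter
    of their combined length, so no pair of planted events can satisfy the
    20%-of-combined-length merge rule: each event is its own locus.
    """
    step = config.step
    lo_steps = math.ceil(config.cnv_length_range[0] / step)
    hi_steps = config.cnv_length_range[1] // step
    lengths = rng.integers(lo_steps, hi_steps + 1, size=config.n_cnvs) * step

    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_names}
    for i in range(config.n_cnvs):
        per_chrom[chrom_names[i % len(chrom_names)]].append(i)

    events: list[dict] = []
    margin = 2 * config.window_size
    for chrom in chrom_names:
        cursor = margin
        prev_len = 0
        for i in per_chrom[chrom]:
            length = int(lengths[i])
            gap_min = margin + math.ceil(0.25 * (prev_len + length) / step) * step
            slack = int(rng.integers(0, 21)) * step
            start = cursor + (gap_min if prev_len else 0) + slack
            end = start + length
            if end + margin > config.chrom_length:
                raise ValueError(
                    f"SimConfig.n_cnvs={config.n_cnvs} exceeds genome capacity "
                    f"on {chrom}"
                )
            events.append({"index": i, "chrom": chrom, "start": start, "end": end})
            cursor = end
            prev_len = length
    events.sort(key=lambda e: e["index"])
    return events


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate read placements, GC track, planted truth and sample map.

    Deterministic for a fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length for c in chrom_names}
    layout = GenomeLayout.from_chrom_sizes(
        sizes, window_size=config.window_size, step=config.step
    )

    samples = [
        f"{pop}_s{i + 1:02d}"
        for pop in config.pop_names
        for i in range(config.samples_per_pop)
    ]
    sample_to_pop = {s: s.rsplit("_s", 1)[0] for s in samples}

    # per-chromosome GC per fine bin
    n_bins = config.bins_per_chrom
    gc_bins: dict[str, np.ndarray] = {}
    for c in chrom_names:
        if config.window_gc_profile is not None:
            prof = np.asarray(config.window_gc_profile, dtype=float)
            if len(prof) != n_bins:
                raise ValueError(
                    "SimConfig.window_gc_profile length must equal bins per chrom"
                )
            gc_bins[c] = prof.copy()
        else:
            gc_bins[c] = _default_gc_profile(n_bins, rng)

    # plant events and assign carriers
    intervals = _plant_events(config, rng, chrom_names) if config.n_cnvs else []
    truth: list[TruthCnv] = []
    n_diff = min(config.n_differentiated, config.n_cnvs)
    diff_ids = set(rng.choice(config.n_cnvs, size=n_diff, replace=False)) \
        if n_diff else set()
    for ev in intervals:
        i = ev["index"]
        differentiated = i in diff_ids
        if differentiated:
            kind = "deletion" if i % 2 == 0 else "duplication"
            freqs = {
                p: (config.differentiated_focal_freq if p == config.focal_pop
                    else config.differentiated_other_freq)
                for p in config.pop_names
            }
        else:
            kind = "deletion" if rng.random() < config.del_fraction else "duplication"
            if config.pop_freq_spec is not None:
                freqs = dict(config.pop_freq_spec[i % len(config.pop_freq_spec)])
            else:
                base = rng.uniform(0.10, 0.45)
                freqs = {
                    p: float(np.clip(base + rng.uniform(-0.08, 0.08), 0.02, 0.6))
                    for p in config.pop_names
                }
        cn_by_sample: dict[str, int] = {}
        for s in samples:
            if rng.random() < freqs[sample_to_pop[s]]:
                if kind == "deletion":
                    cn = 1 if rng.random() < config.het_fraction else 0
                else:
                    cn = 3 if rng.random() < config.dup_cn3_fraction else 4
                cn_by_sample[s] = cn
        truth.append(
            TruthCnv(
                id=f"cnv_{i + 1}",
                chrom=ev["chrom"],
                start=ev["start"],
                end=ev["end"],
                kind=kind,
                copy_number_by_sample=cn_by_sample,
                population_frequencies=freqs,
            )
        )

    # per-sample copy-number track on the fine-bin grid
    cn_tracks = {
        c: np.full((n_bins, len(samples)), 2, dtype=np.int8) for c in chrom_names
    }
    sample_idx = {s: j for j, s in enumerate(samples)}
    for t in truth:
        b0, b1 = t.start // config.step, t.end // config.step
        for s, cn in t.copy_number_by_sample.items():
            cn_tracks[t.chrom][b0:b1, sample_idx[s]] = cn

    scales = rng.lognormal(
        mean=-config.scale_sd**2 / 2, sigma=config.scale_sd, size=len(samples)
    ) if config.scale_sd > 0 else np.ones(len(samples))

    base_rate = config.mean_depth * config.step / config.read_length
    rl = config.read_length
    reads: dict[str, pd.DataFrame] = {}
    for j, s in enumerate(samples):
        chrom_col, start_col = [], []
        for c in chrom_names:
            gc_fac = gc_bias_factor(gc_bins[c], config.gc_bias_strength)
            lam = base_rate * (cn_tracks[c][:, j] / 2.0) * gc_fac * scales[j]
            if config.depth_noise == "poisson":
                counts = rng.poisson(lam)
            else:
                counts = np.rint(lam).astype(np.int64)
            total = int(counts.sum())
            bin_lo = np.repeat(
                np.arange(n_bins, dtype=np.int64) * config.step, counts
            )
            bin_hi = np.minimum(bin_lo + config.step, config.chrom_length)
            mids = bin_lo + np.floor(
                rng.random(total) * (bin_hi - bin_lo)
            ).astype(np.int64)
            starts = np.clip(mids - rl // 2, 0, config.chrom_length - rl)
            chrom_col.append(np.full(total, c, dtype=object))
            start_col.append(starts)
        reads[s] = pd.DataFrame(
            {
                "chrom": np.concatenate(chrom_col),
                "start": np.concatenate(start_col),
                "length": rl,
            }
        )

    # per-window GC from member bins
    wgc = np.empty(layout.n_windows)
    layers = config.window_size // config.step
    for c in chrom_names:
        sl = layout.chrom_slices[c]
        gcb = gc_bins[c]
        ws = layout.window_start[sl] // config.step
        acc = np.zeros(sl.stop - sl.start)
        cnt = np.zeros(sl.stop - sl.start)
        for off in range(layers):
            k = ws + off
            ok = k < n_bins
            acc[ok] += gcb[k[ok]]
            cnt[ok] += 1
        wgc[sl] = acc / cnt

    return Cohort(
        config=config,
        layout=layout,
        reads=reads,
        gc_track=wgc,
        truth=truth,
        sample_to_pop=sample_to_pop,
    )


def simulate_annotations(
    layout: GenomeLayout, n_genes: int, n_qtls: int, seed: int = 0
) -> tuple[list[GeneModel], list[QtlRecord]]:
    """Random gene models (with exons strictly inside the gene span) and
    QTL intervals cycling through the six livestock trait categories."""
    rng = np.random.default_rng(seed)
    chroms = list(layout.chroms)
    genes: list[GeneModel] = []
    cursors = {c: 1000 for c in chroms}
    for i in range(n_genes):
        placed = False
        for attempt in range(len(chroms)):
            c = chroms[(i + attempt) % len(chroms)]
            length = int(rng.integers(5_000, 40_000))
            start = cursors[c] + int(rng.integers(1_000, 20_000))
            end = start + length
            if end + 1000 > layout.chroms[c]:
                continue
            n_ex = int(rng.integers(1, 7))
            interior_lo, interior_hi = start + 50, end - 50
            ex_starts = np.sort(
                rng.choice(
                    np.arange(interior_lo, interior_hi - 200, 200),
                    size=min(n_ex, max(1, (interior_hi - interior_lo) // 400)),
                    replace=False,
                )
            )
            exons = [(int(s), int(s + rng.integers(80, 200))) for s in ex_starts]
            genes.append(
                GeneModel(gene_id=f"gene_{i + 1}", chrom=c, start=start,
                          end=end, exons=exons)
            )
            cursors[c] = end
            placed = True
            break
        if not placed:
            raise ValueError(f"n_genes={n_genes} exceeds genome capacity")
    qtls: list[QtlRecord] = []
    for i in range(n_qtls):
        c = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(20_000, 150_000))
        start = int(rng.integers(0, max(1, layout.chroms[c] - length)))
        qtls.append(
            QtlRecord(
                qtl_id=f"qtl_{i + 1}",
                chrom=c,
                start=start,
                end=start + length,
                category=QTL_CATEGORIES[i % len(QTL_CATEGORIES)],
                trait_name=f"trait_{i + 1}",
            )
        )
    return genes, qtls


def simulate_qpcr(
    truth: list[TruthCnv],
    samples: list[str],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    n_test_samples: int = 3,
    n_replicates: int = 3,
    base_target_ct: float = 24.0,
    reference_ct: float = 20.0,
):
    """Ct tables whose ideal ddCt inversion recovers the planted copy number.

    Target Ct = base - log2(CN/2) + noise; reference-gene Ct is constant up
    to noise. CN=0 carriers amplify at the detection floor (CN ~ 2^-6).
    Each selected event needs >= 1 carrier and >= 1 diploid calibrator.
    Returns (measurements, truth CN per (sample, event id)).
    """
    from .qpcr import QpcrMeasurement

    rng = np.random.default_rng(seed)
    measurements: list[QpcrMeasurement] = []
    truth_cn: dict[tuple[str, str], int] = {}
    for t in truth:
        carriers = [s for s in samples if s in t.copy_number_by_sample]
        diploid = [s for s in samples if s not in t.copy_number_by_sample]
        if not carriers:
            raise ValueError(f"event {t.id}: no carrier among provided samples")
        if not diploid:
            raise ValueError(f"event {t.id}: no CN=2 calibrator sample available")
        chosen = list(rng.choice(carriers, size=min(n_test_samples, len(carriers)),
                                 replace=False))
        calibrator = diploid[int(rng.integers(0, len(diploid)))]
        for s in chosen + [calibrator]:
            cn = t.copy_number_by_sample.get(s, 2)
            truth_cn[(s, t.id)] = cn
            cn_eff = max(cn, 2.0 ** -6)
            tgt = [
                base_target_ct - math.log2(cn_eff / 2.0)
                + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                for _ in range(n_replicates)
            ]
            ref = [
                reference_ct + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                for _ in range(n_replicates)
            ]
            measurements.append(
                QpcrMeasurement(
                    sample=s,
                    target_cnvr_id=t.id,
                    ct_target=tgt,
                    ct_reference=ref,
                    is_calibrator=(s == calibrator),
                )
            )
    return measurements, truth_cn


def evaluate_recovery(
    truth: list[TruthCnv],
    regions,
    layout: GenomeLayout,
    min_carriers: int = 2,
    boundary_tol: int | None = None,
) -> dict:
    """Compare called CNVRs with planted truth.

    A truth event is recoverable when it has >= ``min_carriers`` carriers
    and fully contains >= 2 windows; it is recovered when a called region
    on the same chromosome matches both boundaries within ``boundary_tol``
    (default: one window step). Precision counts called regions matching
    any planted event the same way.
    """
    tol = layout.step if boundary_tol is None else boundary_tol
    w, s = layout.window_size, layout.step

    def n_full_windows(t: TruthCnv) -> int:
        return max(0, (t.length - w) // s + 1)

    eligible = [t for t in truth if t.n_carriers >= min_carriers
                and n_full_windows(t) >= 2]
    regions = list(regions)
    matched_truth: dict[str, str] = {}
    matched_regions: set[str] = set()
    boundary_errors: list[int] = []
    for t in truth:
        for r in regions:
            if (r.chrom == t.chrom and abs(r.start - t.start) <= tol
                    and abs(r.end - t.end) <= tol):
                if t in eligible and t.id not in matched_truth:
                    matched_truth[t.id] = r.id
                    boundary_errors.append(
                        max(abs(r.start - t.start), abs(r.end - t.end))
                    )
                matched_regions.add(r.id)
    recall = len(matched_truth) / len(eligible) if eligible else float("nan")
    precision = (
        len([r for r in regions if r.id in matched_regions]) / len(regions)
        if regions else float("nan")
    )
    return {
        "n_truth": len(truth),
        "n_eligible": len(eligible),
        "n_regions": len(regions),
        "n_recovered": len(matched_truth),
        "recall": recall,
        "precision": precision,
        "max_boundary_error": max(boundary_errors) if boundary_errors else 0,
        "matches": matched_truth,
    }


def write_cohort(cohort: Cohort, outdir) -> None:
    """Serialize a cohort: per-sample read TSVs, GC track, truth BED +
    JSON copy-number sidecar, and the sample->population map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for s, df in cohort.reads.items():
        df.to_csv(os.path.join(outdir, f"reads_{s}.tsv"), sep="\t", index=False)
    gc = pd.DataFrame(
        {
            "chrom": cohort.layout.window_chrom,
            "window_start": cohort.layout.window_start,
            "gc_fraction": np.round(cohort.gc_track, 6),
        }
    )
    gc.to_csv(os.path.join(outdir, "gc_track.tsv"), sep="\t", index=False)
    rows = [
        {"chrom": t.chrom, "start": t.start, "end": t.end, "name": t.id,
         "score": t.n_carriers, "strand": "+", "kind": t.kind}
        for t in cohort.truth
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "truth.bed"), sep="\t", index=False, header=False
    )
    sidecar = {
        t.id: {
            "kind": t.kind,
            "copy_number_by_sample": t.copy_number_by_sample,
            "population_frequencies": t.population_frequencies,
        }
        for t in cohort.truth
    }
    with open(os.path.join(outdir, "truth_cn.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    pd.DataFrame(
        sorted(cohort.sample_to_pop.items()), columns=["sample", "population"]
    ).to_csv(os.path.join(outdir, "sample_map.tsv"), sep="\t", index=False)
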