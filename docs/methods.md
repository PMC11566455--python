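# Methods

## The read-depth model

The pipeline assumes depth of coverage is, after corrections, proportional
to local copy number: a diploid window has normalized depth 1.0, a
single-copy (heterozygous) deletion 0.5, a homozygous deletion 0, a
three-copy duplication 1.5. Two systematic effects break raw
proportionality and are removed in order:

1. **GC bias.** Sequencing depth depends unimodally on local GC content.
   Correction is per sample by bin-median rescaling: windows are binned by
   GC fraction (20 bins), and counts in bin *b* are multiplied by
   `global_median / median(bin b)`. Bins with fewer than 20 windows, or a
   zero median, are left uncorrected; the reference median is taken over
   correctable bins only, and a lower-median (order-statistic) estimator
   is used — together these make the correction exactly idempotent, which
   the tests assert.
2. **Library size.** Each sample is divided by its median depth over
   usable windows. The median (not the mean) is used so that CNV-carrying
   windows do not drag the diploid baseline; it makes normalization
   exactly invariant to a per-sample global rescaling of counts.

Reads are assigned to windows by their midpoint, so each read is counted
once per overlap layer and counts stay Poisson; windows are 800 bp at a
400 bp step (the overlap step is not dictated by the upstream convention
we follow, so it is configurable; half a window is the default because it
halves boundary quantization).

**Window usability mask.** Windows are excluded from calling when their GC
fraction is outside [0.2, 0.8], when fewer than 50% of samples have
nonzero raw depth, or when they are truncated terminal windows (shorter
than the nominal window, hence systematically shallower). An optional trim
of the extreme tails of the cross-sample median relative depth
(`depth_trim_pct`, in percent per tail) is provided for real, artifact-prone
genomes — collapsed repeats and reference errors make most samples deviate
together. It defaults to 0: on clean data, windows where many samples
deviate together are exactly the high-carrier-frequency CNVs, and trimming
them removes true signal (measured on the benchmark cohort, a 0.5% trim
masked the strongest planted deletions and cut recall from 1.0 to 0.86).

## Calling and merging

Thresholds follow the read-depth caller convention: normalized depth
below 0.2 → homozygous deletion; [0.2, 0.7) → heterozygous deletion
(half-open boundaries, deterministic tie-break); above `dup_floor` →
duplication. Only the deletion-side limits are conventionally specified;
the duplication floor defaults to 2 − 0.7 = 1.3 by symmetry and is
configurable. States are assigned per window; a segment's state is
re-checked on its mean (a deletion run whose mean is below 0.2 is reported
homozygous).

Per-sample segmentation joins same-direction non-neutral windows, allowing
at most one neutral/masked window inside a run, and discards runs with
fewer than two non-neutral windows. Opposite directions never join.

Cross-sample merging agglomerates calls into CNVRs, left-to-right within
each chromosome and repeated to a fixed point. Two candidate regions merge
iff (a) the gap between them is less than 20% of their combined length
(overlap ⇒ gap ≤ 0), and (b) the Pearson correlation between the two
regions' per-sample mean-depth vectors is significant at the 0.01 level
(exact two-sided t test on r with n − 2 degrees of freedom). Identical
spans merge unconditionally (they are the same window set, where the test
degenerates). With fewer than 4 samples the test has no degrees of
freedom, and merging falls back to the gap rule with a warning. A region's
member windows are the windows fully contained in its span (spans are
unions of windows); boundary-straddling windows mix flanking diploid
signal and are excluded from region depth vectors and copy numbers, which
is what makes zero-noise copy numbers exact.

Filtering keeps CNVRs with ≥ 2 carriers (`min_samples`; the stricter
"more than two" reading is available as `min_samples=3`) on whitelisted
(placed) chromosomes. Type is *deletion*/*duplication* when all carrier
states agree in direction, *mixed* otherwise.

## V_ST

For each CNVR, continuous copy numbers CN = 2 × mean normalized depth over
member windows are split into a focal group and the pooled remainder, and

    V_ST = (V_T - V_S) / V_T

with V_T the pooled variance and V_S = (n1·v1 + n2·v2)/(n1+n2). Population
variances (ddof = 0) are the default, matching the Redon-style convention;
ddof = 1 is exposed because conventions differ, and the sign of small
V_ST values can flip between the two (the tests pin both on a worked
example). Records with V_T = 0 carry no differentiation signal and are
flagged undefined and excluded from the top-fraction quantile; ties at the
top-5% threshold are all selected. V_ST ≤ 1 always; negative values are
retained, not clamped.

## qPCR arithmetic

ΔCt = mean(target Ct) − mean(reference Ct) per sample (replicates averaged
arithmetically); ΔΔCt = ΔCt(sample) − ΔCt(calibrator); CN = 2 × 2^−ΔΔCt,
assuming amplification efficiency exactly 2. Class boundaries: loss when
CN ≤ 1.5, gain when CN ≥ 3.0 (verbal "around 0 or 1" / "around three or
higher" thresholds made explicit and configurable). A CNVR batch needs
exactly one diploid calibrator and validates when all test samples'
classes match the sequencing states. The estimator is invariant to any
global Ct shift.

## The synthetic cohort

The generator emulates what the pipeline relies on, not sequencing itself:

- 5 chromosomes × 1 Mb, smooth isochore-like GC landscape (~[0.3, 0.65],
  long-period waves so adjacent windows have similar GC);
- 3 populations × 10 samples at mean depth 15X, 100 bp uniform-start
  reads, per-window Poisson counts with rate
  `mean_depth · step/read_length · (CN/2) · gc_bias(GC) · sample_scale`;
- a unimodal multiplicative GC-depth bias peaking at GC = 0.5
  (strength 0.3 by default) and log-normal per-sample library scales
  (σ = 0.1), so both correction stages do real work;
- 60 planted CNVs of 3.2–16 kb aligned to the step grid; deletions 55%
  (carriers 80% heterozygous / 20% homozygous), duplications (80% CN 3 /
  20% CN 4); carrier frequencies drawn per population around a shared base
  (U(0.10, 0.45) ± 0.08), so events are polymorphic but rarely
  majority-carrier;
- 3 events differentiated in the focal population (carrier frequency 0.9
  vs 0.02 elsewhere) to give the V_ST scan recoverable signal;
- planted events are separated by at least two windows plus a quarter of
  the combined length of neighbouring events, so no pair of truth events
  can satisfy the 20%-gap merge rule: each planted event is one locus, and
  recovery can be scored per event;
- `depth_noise="none"` replaces Poisson draws by rounded expectations,
  giving exactly CN/2 normalized depth for zero-noise oracle tests.

What it does *not* model: sequencing errors, mappability/repeat structure,
alignment artifacts, dispersion beyond Poisson, shared breakpoints between
overlapping events, or sex chromosomes. Passing recovery tests therefore
show the calling/merging logic is correct under the read-depth model's own
assumptions — not that real-genome artifact handling (which is what the
optional depth trim and mask rules are for) is sufficient.

Recovery scoring: an event is *recoverable* when it has ≥ `min_samples`
carriers (the frequency filter is working as designed otherwise) and fully
contains ≥ 2 windows; it is *recovered* when a called CNVR matches both
boundaries within one window step. At zero noise the boundary error is
structural: a heterozygous deletion's edge window (half inside) has depth
0.75 → neutral, so boundaries are exact; homozygous deletions (edge 0.5 →
het) and CN = 4 duplications (edge 1.5 → dup) extend one step. Precision
counts called regions matching any planted event the same way.

## Numerical and interface choices

- Coordinates are 0-based half-open everywhere internally and in BED-like
  outputs; 1-based only in human-readable text.
- Percentages are rounded half-up (not banker's) to the stated decimals.
- Quantiles for the top-fraction selection use numpy's default linear
  interpolation; with 100 distinct values exactly 5 exceed the 95%
  threshold.
- The interval index is a sorted-starts/prefix-max-ends structure with
  O(log n) existence queries; all interval operations are verified against
  a naive pairwise scan in the tests.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical config + seed gives byte-identical
  outputs, which the pipeline tests assert at file level.
- The benchmark problem size (5 Mb genome, 30 samples, ~22 M reads) keeps
  a full end-to-end run around 15 s while leaving ≥ 1000 windows per
  chromosome for stable medians; all statistical checks are run at this
  size.

## Known limitations

- Merging compares adjacent-by-start candidates only; a region pair whose
  gap rule is satisfied only via a third, non-mergeable region in between
  will stay separate. On well-separated loci this is the desired
  behaviour.
- The per-region carrier state is taken from each sample's largest member
  call; a sample with genuinely both a deletion and a duplication inside
  one CNVR is summarized by the larger event.
- CN = 0 carriers cannot produce a finite qPCR Ct; the generator amplifies
  them at a detection floor (CN 2⁻⁶), matching how no-amplification wells
  are handled in practice.
- Real-data mode consumes read-placement TSVs (chrom, start, length), a
  deliberate simplification of alignment files; converting BAM/CRAM to
  that form is out of scope here.
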