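# rdcnv

Read-depth copy-number-variation (CNV) analysis for whole-genome-sequenced
cohorts: windowed GC-corrected depth, per-sample CNV calling, cross-sample
CNV-region (CNVR) merging, genic/QTL annotation and breed-sharing
summaries, a V<sub>ST</sub> population-differentiation scan, and qPCR
ΔΔCt validation arithmetic. A synthetic-cohort generator with planted CNVs
makes every stage testable end to end without any sequencing data.

The package is aimed at population/livestock genomicists who want a small,
fully-tested reference implementation of the classic read-depth CNV
pipeline (the CNVcaller-style workflow) whose behaviour can be verified
against planted truth.

## Method

**Depth and normalization.** The genome is tiled with overlapping sliding
windows (800 bp, step 400 bp). Each read counts toward every window
containing its midpoint, keeping per-window counts Poisson. Depth is then
(i) GC-corrected per sample by bin-median rescaling (windows binned by GC
fraction; each bin scaled so its median matches the genome-wide median)
and (ii) divided by the sample's median over usable windows, so a diploid
window sits at normalized depth 1.0 and copy number ≈ 2 × normalized depth.

**Calling.** Per window and sample: normalized depth < 0.2 → homozygous
deletion, [0.2, 0.7) → heterozygous deletion, > 1.3 (= 2 − 0.7, by
symmetry) → duplication. Same-direction runs of ≥ 2 windows (one neutral
gap window tolerated) become per-sample calls. Calls from all samples are
agglomerated into CNVRs: two candidate regions merge when the gap between
them is < 20% of their combined length *and* the Pearson correlation of
their per-sample depth profiles is significant at the 0.01 level, repeated
to a fixed point. CNVRs carried by fewer than 2 samples, or on unplaced
scaffolds, are dropped; a CNVR is a *deletion*, *duplication*, or *mixed*
according to its carriers' states.

**Differentiation.** Per CNVR, with continuous copy numbers
CN = 2 × mean normalized depth,

&nbsp;&nbsp;&nbsp;&nbsp;V<sub>ST</sub> = (V<sub>T</sub> − V<sub>S</sub>) / V<sub>T</sub>,

where V<sub>T</sub> is the variance of CN pooled over the two groups and
V<sub>S</sub> the population-size-weighted mean within-group variance
(population variances, ddof = 0). The top 5% of the V<sub>ST</sub>
distribution is reported as candidate differentiated regions.

**qPCR validation.** Copy number is estimated as 2 × 2<sup>−ΔΔCt</sup>
against a diploid calibrator (ΔCt = target − reference-gene Ct). Estimates
≤ 1.5 are losses, ≥ 3.0 gains, otherwise normal; a region validates when
qPCR classes match the sequencing-derived states.

## Worked example

The numbered scripts under `analysis/` run the whole study on the built-in
benchmark cohort (3 populations × 10 samples at ~15X over a 5 Mb toy
genome, 60 planted CNVs, 3 of them strongly differentiated in `pop3`):

```sh
cd analysis
python 01_simulate_cohort.py
python 03_call_cnvrs.py
python 05_vst_scan.py
```

prints (abridged):

```
reads: 22,406,215 total (~14.9X per sample)
planted: 60 CNVs (34 deletions, 26 duplications; 3 differentiated in pop3)

574 per-sample calls -> 58 CNVRs ({'deletion': 29, 'duplication': 26, 'mixed': 3})
recovery: recall 0.983, precision 0.983, max boundary error 400 bp (57/58 recoverable events)

V_ST scan: pop3 vs pooled rest; 58 defined records
top-5% threshold: 0.1994; 3 CNVRs selected: ['cnvr_21', 'cnvr_4', 'cnvr_9']
planted differentiated events in top 5%: 3/3
```

Reading: of the 60 planted events, 58 had at least two carriers and span
two windows (the rest cannot pass the ≥ 2-sample filter by design); the
caller recovered 57 of them with boundaries within one window step, with
one false region — recall and precision 0.983. The three planted
fixed-difference events all land in the top 5% of the V<sub>ST</sub> scan.
`04_annotate_cnvrs.py` and `06_qpcr_validation.py` add the annotation
summaries and the ΔΔCt concordance table. The same pipeline runs from the
shell via the `rdcnv` CLI (`rdcnv run-all`, `rdcnv simulate`, `rdcnv
depth`, `rdcnv call`, `rdcnv vst`, `rdcnv qpcr`) on TSV inputs.

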