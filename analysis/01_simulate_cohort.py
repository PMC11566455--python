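"""Generate the benchmark cohort and summarize what was planted.

Three populations x 10 samples at ~15X over a 5 x 1 Mb toy genome, with 60
planted CNVs (population-stratified carrier frequencies; three events are
strongly differentiated in the focal population pop3).
"""

import os

import pandas as pd

import _common

coh = _common.cohort()
out = _common.outdir()

truth = pd.DataFrame(
    [
        {
            "id": t.id, "chrom": t.chrom, "start": t.start, "end": t.end,
            "length": t.length, "kind": t.kind, "n_carriers": t.n_carriers,
            "focal_freq": t.population_frequencies[coh.config.focal_pop],
        }
        for t in coh.truth
    ]
)
truth.to_csv(os.path.join(out, "planted_truth.tsv"), sep="\t", index=False)

n_reads = sum(len(df) for df in coh.reads.values())
print(f"cohort: {len(coh.samples)} samples in "
      f"{sorted(set(coh.sample_to_pop.values()))}")
print(f"genome: {len(coh.layout.chroms)} chromosomes, "
      f"{sum(coh.layout.chroms.values()) / 1e6:.0f} Mb, "
      f"{coh.layout.n_windows} windows")
print(f"reads: {n_reads:,} total "
      f"(~{n_reads * coh.config.read_length / sum(coh.layout.chroms.values()) / len(coh.samples):.1f}X per sample)")
print(f"planted: {len(coh.truth)} CNVs "
      f"({(truth['kind'] == 'deletion').sum()} deletions, "
      f"{(truth['kind'] == 'duplication').sum()} duplications; "
      f"{(truth['focal_freq'] > 0.8).sum()} differentiated in "
      f"{coh.config.focal_pop})")
print(f"wrote {out}/planted_truth.tsv")
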