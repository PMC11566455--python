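"""Per-sample CNV calls, CNVR merging/filtering, and recovery vs truth.

Produces the CNVR table, the per-breed summary (count, length, unique,
type breakdown, % of genome), and the recall/precision of the caller
against the planted events.
"""

import json
import os

from rdcnv import calling, pipeline

import _common

res = _common.result()
out = _common.outdir()

df = calling.regions_to_frame(res.regions)
df.to_csv(os.path.join(out, "cnvrs.tsv"), sep="\t", index=False)
summary = pipeline.population_summary(res)
summary.to_csv(os.path.join(out, "summary_by_population.tsv"), sep="\t",
               index=False)
with open(os.path.join(out, "recovery.json"), "w") as fh:
    json.dump({k: v for k, v in res.recovery.items() if k != "matches"},
              fh, indent=1)

types = df["type"].value_counts().to_dict()
rec = res.recovery
print(f"{len(res.calls)} per-sample calls -> {len(res.regions)} CNVRs "
      f"({types})")
print(summary.to_string(index=False))
print(f"recovery: recall {rec['recall']:.3f}, precision {rec['precision']:.3f},"
      f" max boundary error {rec['max_boundary_error']} bp "
      f"({rec['n_recovered']}/{rec['n_eligible']} recoverable events)")
print(f"wrote cnvrs.tsv, summary_by_population.tsv, recovery.json in {out}")
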