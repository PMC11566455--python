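"""Genic context, size distribution, breed sharing and QTL overlap of the
called CNVRs (against the simulated gene/QTL annotation)."""

import json
import os

import pandas as pd

import _common

res = _common.result()
out = _common.outdir()

labels = pd.Series(res.genic_labels)
genic = labels.value_counts().reindex(
    ["exonic", "intronic", "intergenic"], fill_value=0
)
res.size_table.to_csv(os.path.join(out, "size_distribution.tsv"), sep="\t",
                      index=False)
with open(os.path.join(out, "breed_sharing.json"), "w") as fh:
    json.dump({k: v for k, v in res.sharing.items() if k != "membership"},
              fh, indent=1, sort_keys=True)
with open(os.path.join(out, "qtl_overlap.json"), "w") as fh:
    json.dump({k: v for k, v in res.qtl_summary.items()
               if k != "hits_per_region"}, fh, indent=1, sort_keys=True)

total = len(res.regions)
print("genic context:", {k: f"{v} ({100 * v / total:.1f}%)"
                         for k, v in genic.items()})
print("size bins:")
print(res.size_table.to_string(index=False))
print("breed sharing (Venn cells):", res.sharing["venn_cells"])
print("unique per population:", res.sharing["unique"])
q = res.qtl_summary
print(f"QTL overlap: {q['n_overlapping']}/{q['n_cnvrs_total']} CNVRs "
      f"({q['pct_overlapping']}%) hit {q['n_qtls_hit']} QTLs; "
      f"category %: {q['per_category_pct']}")
print(f"wrote size_distribution.tsv, breed_sharing.json, qtl_overlap.json in {out}")
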