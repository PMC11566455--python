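"""Window depth, GC correction and per-sample scaling on the benchmark.

Checks the two properties calling relies on: the diploid baseline sits at
1.0 per sample, and depth in planted-event windows tracks CN/2.
"""

import os

import numpy as np
import pandas as pd

import _common

coh = _common.cohort()
res = _common.result()
m = res.matrix
out = _common.outdir()

medians = np.median(m.normalized[m.window_mask, :], axis=0)
stats = pd.DataFrame({
    "sample": m.samples,
    "median_normalized": np.round(medians, 4),
    "mean_raw_count": np.round(m.raw.mean(axis=0), 2),
})
stats.to_csv(os.path.join(out, "sample_depth_stats.tsv"), sep="\t", index=False)

lay = m.layout
errs = []
for t in coh.truth:
    idx = lay.windows_within(t.chrom, t.start, t.end)
    idx = idx[m.window_mask[idx]]
    for s, cn in t.copy_number_by_sample.items():
        obs = m.normalized[idx, m.sample_index(s)].mean()
        errs.append(obs - cn / 2)
errs = np.asarray(errs)

print(f"mask: {m.window_mask.sum()}/{lay.n_windows} windows usable")
print(f"per-sample diploid median in [{medians.min():.4f}, {medians.max():.4f}]"
      f" (target 1.0 +/- 0.05)")
print(f"carrier windows: mean |depth - CN/2| = {np.abs(errs).mean():.4f} "
      f"(max {np.abs(errs).max():.4f})")
print(f"wrote {out}/sample_depth_stats.tsv")
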