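"""Shared setup for the analysis drivers: the benchmark cohort and the
fitted pipeline, rebuilt deterministically from one seed."""

import functools
import os

from rdcnv import pipeline, simulate

SEED = 7
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


@functools.lru_cache(maxsize=1)
def cohort():
    return simulate.simulate_cohort(simulate.SimConfig(seed=SEED))


@functools.lru_cache(maxsize=1)
def result():
    cfg = pipeline.PipelineConfig(seed=SEED)
    return pipeline.run_from_cohort(cohort(), cfg)


def outdir() -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return RESULTS
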