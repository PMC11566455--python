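import numpy as np
import pytest

from rdcnv import depth, pipeline, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """The standard benchmark cohort: 5 x 1 Mb genome, 3 populations x 10
    samples at 15X Poisson noise, 60 planted CNVs (3 differentiated)."""
    return simulate.simulate_cohort(simulate.SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    cfg = pipeline.PipelineConfig(seed=7)
    return pipeline.run_from_cohort(default_cohort, cfg)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small deterministic cohort: expected counts instead of Poisson, no
    GC bias, no library-scale variation -> depth is exactly CN/2."""
    cfg = simulate.SimConfig(
        n_chroms=2,
        chrom_length=400_000,
        samples_per_pop=4,
        n_cnvs=8,
        n_differentiated=0,
        depth_noise="none",
        gc_bias_strength=0.0,
        scale_sd=0.0,
        seed=5,
    )
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def zero_noise_matrix(zero_noise_cohort):
    m = depth.compute_window_depth(zero_noise_cohort.reads, zero_noise_cohort.layout)
    m = depth.gc_normalize(m, zero_noise_cohort.gc_track)
    return depth.sample_normalize(m)


def make_matrix(nd, window_size=400, step=400, chrom="chr1", mask=None):
    """DepthMatrix with a given normalized layer (windows x samples)."""
    nd = np.asarray(nd, dtype=float)
    n_windows, n_samples = nd.shape
    layout = depth.GenomeLayout(
        chroms={chrom: n_windows * step}, window_size=window_size, step=step
    )
    samples = [f"s{j + 1}" for j in range(n_samples)]
    return depth.DepthMatrix(
        layout=layout,
        samples=samples,
        raw=nd.copy(),
        normalized=nd,
        window_mask=np.ones(n_windows, bool) if mask is None else np.asarray(mask),
    )
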