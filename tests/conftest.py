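import numpy as np
import pytest

import depotatac as da


@pytest.fixture(scope="session")
def sim_config():
    return da.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    return da.simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def dataset_dir(sim_dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("dataset")
    da.write_dataset(sim_dataset, d)
    return d


@pytest.fixture(scope="session")
def pipeline_out(dataset_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = da.PipelineConfig.for_dataset_dir(dataset_dir, out, write_tracks=False)
    report = da.run_pipeline(cfg)
    return report, out


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), span=10_000, max_len=300):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(da.GenomicInterval(chrom, start, start + length))
    return out
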