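import numpy as np
import pandas as pd
import pytest

from histodiff.bin_signal import BinGrid
from histodiff.synthetic_data import SyntheticConfig, make_genome, plant_truth


def make_reads(records):
    """Reads DataFrame from (chrom, start, end, strand) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "strand"])
    df["name"] = [f"r{i}" for i in range(len(df))]
    df["score"] = 0
    return df[["chrom", "start", "end", "name", "score", "strand"]]


@pytest.fixture
def small_grid():
    return BinGrid({"chr1": 10_000}, width=500)


@pytest.fixture(scope="session")
def tiny_config():
    return SyntheticConfig(
        n_chroms=1,
        chrom_length=200_000,
        n_genes=8,
        reads_per_sample=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    annotation = make_genome(tiny_config)
    truth = plant_truth(annotation, tiny_config)
    return annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
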