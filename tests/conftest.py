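import numpy as np
import pandas as pd
import pytest

from spikequant import (
    BinMatrix,
    ChipSimParams,
    Interval,
    RnaSimParams,
    simulate_chip_experiment,
    simulate_rna_experiment,
)


@pytest.fixture(scope="session")
def small_chip_sim():
    """A small two-condition spike-in ChIP simulation (r_global = 0.5)."""
    params = ChipSimParams(
        n_bins=800, depth=200_000, n_replicates=2, r_global=0.5,
        spike_fraction=0.1, domain_spec=[(100, 30, 3.0)], seed=11,
    )
    splits, bins, truth = simulate_chip_experiment(params)
    return params, splits, bins, truth


@pytest.fixture(scope="session")
def small_rna_sim():
    """A small ERCC-spiked RNA simulation with a global doubling (g_global = 2)."""
    params = RnaSimParams(
        n_genes=800, depth=400_000, n_replicates=3, g_global=2.0, seed=7
    )
    counts, truth = simulate_rna_experiment(params)
    return params, counts, truth


def make_bin_matrix(values: np.ndarray, columns=None, width: int = 10_000) -> BinMatrix:
    """Helper: wrap a (bins x samples) array on a single test chromosome."""
    values = np.atleast_2d(values)
    if values.shape[1] < values.shape[0] and values.ndim == 2 and columns is not None:
        pass
    n_bins = values.shape[0]
    columns = columns or [f"s{i}" for i in range(values.shape[1])]
    bins = [Interval("chrT", i * width, (i + 1) * width) for i in range(n_bins)]
    return BinMatrix(bins=bins, counts=pd.DataFrame(values, columns=columns))
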