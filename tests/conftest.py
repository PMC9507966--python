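import numpy as np
import pandas as pd
import pytest

from hp5kit.synthetic_data import (
    SimConfig,
    generate_reference,
    plant_truth,
    simulate_end5_counts,
    simulate_polysome_experiment,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=20, library_size=300_000, seed=7)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_reference):
    _, annotation = small_reference
    return plant_truth(annotation, small_config)


@pytest.fixture(scope="session")
def small_tracks(small_config, small_reference, small_truth):
    return simulate_end5_counts(small_reference, small_truth, small_config)


@pytest.fixture(scope="session")
def small_polysome(small_config, small_truth):
    return simulate_polysome_experiment(small_truth, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_track(positions, counts, g_fractions=None, chrom="chr1", strand="+"):
    """Helper: build an in-memory 5'-end track from parallel arrays."""
    positions = np.asarray(positions, dtype=int)
    counts = np.asarray(counts, dtype=int)
    if g_fractions is None:
        g_fractions = np.full(len(positions), 0.6)
    return pd.DataFrame(
        dict(chrom=chrom, pos=positions, strand=strand,
             count=counts, g_fraction=np.asarray(g_fractions, dtype=float))
    )
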