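import pandas as pd
import pytest

from cilseq.synthetic import SimConfig, simulate_clone_tree


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast configuration for tests that only need structure, not scale."""
    return SimConfig(seed=7, n_cpg=3000, n_noncpg=2000, n_genes=40,
                     n_spots_per_type=20, n_spot_genes=60)


@pytest.fixture(scope="session")
def default_tree(default_config):
    return simulate_clone_tree(default_config)


def make_calls(rows) -> pd.DataFrame:
    """Build a variant table from (chrom, pos, ref, alt, sample, callers,
    depth, alt_reads) tuples."""
    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "sample_id", "callers", "depth",
        "alt_reads"])
    df["af"] = df["alt_reads"] / df["depth"]
    return df
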