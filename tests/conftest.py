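import numpy as np
import pandas as pd
import pytest

from ogmap.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=7, n_chroms=2, chrom_length=120_000, n_genes=24)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_cfg):
    """A small synthetic study bundle shared across pipeline-level tests."""
    out = tmp_path_factory.mktemp("bundle")
    simulate_bundle(small_cfg, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def intervals(*rows):
    """Shorthand interval DataFrame builder for tests."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
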