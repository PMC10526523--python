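import numpy as np
import pandas as pd
import pytest

from xaber import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-sample cohort under generator defaults, shared across tests."""
    return synthdata.generate_cohort(synthdata.SimConfig(n_samples=200, seed=7))


@pytest.fixture(scope="session")
def small_bins(small_cohort):
    from xaber import xcna

    cfg = small_cohort.config
    return xcna.make_bins(cfg.n_bins, cfg.bin_size_bp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_gene_models():
    return pd.DataFrame(
        {
            "gene": ["G1", "G2", "G3"],
            "chromosome": ["chrX", "chrX", "chrX"],
            "tss": [10_000, 50_000, 90_000],
            "strand": ["+", "-", "+"],
            "region_tags": ["PAR1", "", ""],
        }
    )
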