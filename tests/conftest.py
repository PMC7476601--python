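import numpy as np
import pandas as pd
import pytest

from glycoquant import fixtures, pipeline


@pytest.fixture(scope="session")
def noiseless_fixture(tmp_path_factory):
    """Standard planted experiment: 3 proteins, 6 sites, 2x3 samples, no noise."""
    truth = fixtures.default_truth(seed=42, noise_sd=0.0, redundancy=2, decoy_rate=0.1)
    outdir = tmp_path_factory.mktemp("noiseless")
    return fixtures.generate(truth, outdir)


@pytest.fixture(scope="session")
def noiseless_pairs(noiseless_fixture):
    return pipeline.load_sample_map(noiseless_fixture.sample_map)


@pytest.fixture(scope="session")
def site_result(noiseless_pairs):
    return pipeline.run_pipeline(noiseless_pairs, mode="site")


@pytest.fixture(scope="session")
def peptide_result(noiseless_pairs):
    return pipeline.run_pipeline(noiseless_pairs, mode="peptide")


@pytest.fixture(scope="session")
def truth_table(noiseless_fixture):
    return pd.read_csv(noiseless_fixture.truth_table, keep_default_na=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
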