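import numpy as np
import pytest

from mirpair import SyntheticConfig, generate_dataset, generate_sequences


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down 7v7 design with planted DE features and pairs."""
    return SyntheticConfig(
        n_mrna=400, n_mirna=60, n_de_mrna=40, n_de_mirna=8, n_distinct=6,
        n_true_pairs=8, noise_sd=0.5, log_fc_mean=2.0, utr_len=300, seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    """(mRNA dataset, miRNA dataset, truth) for the small design."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_sequences(small_config, small_data):
    _, _, truth = small_data
    return generate_sequences(small_config, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
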