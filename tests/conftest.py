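import pytest

from p53screen.synthetic_data import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=120, n_true_repressed=10, n_prognostic=5,
        cohort_n=(160, 70), seed=7,
    )


@pytest.fixture(scope="session")
def noisefree_config(small_config):
    from dataclasses import replace

    return replace(small_config, noise_sd_log=0.0, ct_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def noisefree_bundle(noisefree_config):
    return simulate_bundle(noisefree_config)
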