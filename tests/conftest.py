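import numpy as np
import pytest

from trimscope.config import NoiseConfig, SimConfig
from trimscope.pipeline import run_knockdown_experiment
from trimscope.simulate import sample_population, simulate_field


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small two-round field that renders in well under a second."""
    return SimConfig(
        n_cells=40,
        field_shape=(256, 256),
        rounds=(("Hoechst", "Ab", "Target"), ("Hoechst", "pP65")),
        phospho_link={"pP65": __import__("trimscope").PhosphoLink()},
        seed=7,
    )


@pytest.fixture(scope="session")
def noisefree_config(small_config: SimConfig) -> SimConfig:
    return small_config.replace(
        noise=NoiseConfig.off(), shift_px_sd=0.0, bleach_carryover=0.0
    )


@pytest.fixture(scope="session")
def noisefree_field(noisefree_config):
    gt = sample_population(noisefree_config)
    from trimscope.simulate import render_rounds

    return gt, render_rounds(gt, noisefree_config)


@pytest.fixture(scope="session")
def small_field(small_config):
    return simulate_field(small_config)


@pytest.fixture(scope="session")
def mtor_run():
    """A moderate end-to-end mTOR run reused by analysis/embedding tests."""
    return run_knockdown_experiment(
        "mTOR-12h", n_cells_per_condition=700, seed=5, n_boot=50,
        modes=("bulk", "gated"),
    )
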