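import numpy as np
import pytest

from impedquant import (GeneratorConfig, SplitSpec, assay_regime, null_regime,
                        simulate_study)
from impedquant.tables import make_peak_table


@pytest.fixture(scope="session")
def preset() -> GeneratorConfig:
    return assay_regime()


@pytest.fixture(scope="session")
def null_preset() -> GeneratorConfig:
    return null_regime()


@pytest.fixture(scope="session")
def small_study(preset):
    """A small 5-concentration study: 3 experiments x 150 beads per class."""
    design = {c: (3, 150) for c in (0.0, 10.0, 50.0, 100.0, 500.0)}
    return simulate_study(preset, design, seed=421)


@pytest.fixture
def spec():
    return SplitSpec(seed=99)


def single_class_table(n_rows: int, concentration: float = 0.0,
                       n_channels: int = 8, seed: int = 0):
    """A labeled peak table with random non-negative amplitudes."""
    rng = np.random.default_rng(seed)
    amps = rng.uniform(0.05, 0.4, size=(n_rows, n_channels))
    return make_peak_table(amps, concentration, "chipX", f"exp-{seed}")
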