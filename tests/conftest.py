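import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def classification_results():
    """Held-out classification benchmark on default synthetic tiles.

    Session-scoped: the tile rendering + detection pass is the most
    expensive computation in the suite and several tests consume it.
    """
    from tilquant import validation

    return validation.classification_benchmark(seed=0)


@pytest.fixture(scope="session")
def reference_tile():
    """A noise-free 200x200 um default tile with its ground truth."""
    from tilquant.synthetic import SimulationConfig, render_tile, sample_cell_layout

    cfg = SimulationConfig(seed=0, field_um=(200.0, 200.0))
    layout = sample_cell_layout(cfg)
    rgb, truth = render_tile(layout, noise_sd=0.0)
    return rgb, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
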