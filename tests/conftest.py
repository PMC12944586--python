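import numpy as np
import pytest

from vegdrivers.synthetic import (PredictorSpec, SyntheticPanelConfig,
                                  generate_panel)


@pytest.fixture(scope="session")
def small_panel():
    """A compact varying-coefficient panel for GTWR unit tests."""
    cfg = SyntheticPanelConfig(
        n_units=12, years=(2000, 2014), domain=(300.0, 200.0),
        predictors=(
            PredictorSpec("a", 0.0, 1.0, (0.5, 1e-3, -8e-4, 0.02)),
            PredictorSpec("b", 0.0, 1.0, (-0.3, -8e-4, 1e-3, -0.015)),
        ),
        noise_sd=0.05, seed=11)
    return generate_panel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
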