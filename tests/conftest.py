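import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "chemosig",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("chemosig")

# the suite deliberately exercises warning paths (short signatures, drops)
logging.getLogger("chemosig").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_plate():
    """Exact logistic plate: true IC50 on the dose grid, no noise."""
    from chemosig import PlateSimConfig, generate_dose_response

    cfg = PlateSimConfig(true_ic50=10.0, hill_slope=1.0,
                         concentrations=(0.1, 1.0, 3.0, 10.0, 30.0, 100.0),
                         n_replicates=3, noise_cv=0.0, seed=0)
    return generate_dose_response(cfg)


@pytest.fixture
def small_panel():
    """Default simulated panel (47 lines, 20+20 planted at |r| = 0.7)."""
    from chemosig import PanelSimConfig, generate_panel

    return generate_panel(PanelSimConfig(seed=11))
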