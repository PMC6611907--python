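import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

import eitdect as e


@pytest.fixture(scope="session")
def small_spec():
    """Noise-free phantom on a coarse grid (same 96 mm geometry)."""
    return e.PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(2.0, 2.0, 2.0), noise_sd_hu=0.0)


@pytest.fixture(scope="session")
def uniform_step():
    """Two-lung step with uniform quadrant air fractions 0.3 -> 0.5."""
    return e.ProtocolStep(
        "T01",
        peep_cmH2O=5.0,
        tv_ml=600.0,
        quadrant_air_fraction_exp=(0.3, 0.3, 0.3, 0.3),
        quadrant_air_fraction_insp=(0.5, 0.5, 0.5, 0.5),
    )


@pytest.fixture(scope="session")
def phantom_pair(small_spec, uniform_step):
    """(insp, exp, truth) for the uniform noise-free phantom."""
    return e.generate_ct_pair(small_spec, uniform_step, seed=11)
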