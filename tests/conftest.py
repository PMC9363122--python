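import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from osteosim.datasets import build_hybrid
from osteosim.fixtures import FixtureSpec, generate_dataset
from osteosim.parameters import reference_parameters

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def noise_free_denosumab_hybrid(ref_params):
    """Noise-free synthetic denosumab study merged into its aging context.

    Treatment starts at a bin-center age (65) so the hybrid pipeline's
    linear baseline-anchor interpolation is exact and the generating
    parameters are the exact optimum of the calibration objective.
    """
    spec = FixtureSpec(
        "denosumab-noise-free",
        [("denosumab", 60, 0.5, 2)],
        start_age=65,
        bmd_noise_sd=0.0,
        btm_noise_sd=0.0,
        bmd_visits=(0.0, 0.5, 1.0, 1.5, 2.0),
        btm_visits=(0.0, 0.25, 0.5, 1.0, 2.0),
    )
    treatment, aging = generate_dataset(spec, ref_params)
    return build_hybrid(aging, treatment)
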