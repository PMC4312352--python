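import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from admixpower import PanelSpec, generate_reference_panels


@pytest.fixture(scope="session")
def bn_panels():
    """Two Balding–Nichols panels (F=0.1, 5000 markers, 50 individuals)."""
    freqs, panels, truth = generate_reference_panels(PanelSpec(seed=0))
    return freqs, panels, truth


@pytest.fixture(scope="session")
def small_model():
    """Scaled-down demographic model for fast simulator tests."""
    from admixpower import DemographicModel

    return DemographicModel(
        t_start=120,
        t_split1=60,
        t_split2=30,
        t_pulse=10,
        N_anc1=300,
        N_source=400,
        N_control=150,
        N_admix=150,
        n_loci=300,
        n_chromosomes=6,
        sample_size=20,
        pulse_rate=0.10,
    )
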