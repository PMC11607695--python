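import numpy as np
import pytest

from plungedee.dlw import IsotopePanel
from plungedee.simulate import SimScenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def example_panel():
    """Panel matching the hand-evaluated worked examples (T_eff = 47 h)."""
    return IsotopePanel(
        I_bg_d=150.0, I_bg_o=150.0,
        I_init_d=2000.0, I_init_o=2000.0,
        I_final_d=500.0, I_final_o=500.0,
        I_inj_d=90000.0, I_inj_o=90000.0,
        mol_inj=0.05, t_total_h=48.0, equilibration_h=1.0)


@pytest.fixture
def clean_scenario():
    """Noise-free study conditions for exact round-trip checks."""
    return SimScenario(seed=42, n_deployed_birds=5,
                       dee_noise_cv=0.0, enrichment_noise_cv=0.0,
                       equilibrium_scatter_cv=0.0)


@pytest.fixture
def small_scenario():
    """Reduced cohort for fast pipeline-level tests."""
    return SimScenario(seed=7, n_equilibrium_birds=6, n_deployed_birds=8,
                       deployment_hours=(24.0, 30.0))
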