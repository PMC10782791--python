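import numpy as np
import pytest

from qpcrf0 import ModelParams, SimulationDesign, simulate_curve, simulate_dilution_series


@pytest.fixture
def clean_params():
    """A realistic noise-free parameter set with drifting baseline."""
    return ModelParams(f_m=1.0, D=1.5, E=1.85, C_i=22.0, a=0.001, b=0.05)


@pytest.fixture
def clean_curve(clean_params):
    return simulate_curve(clean_params, noise_sd=0.0, n_cycles=40, seed=0)


@pytest.fixture
def noiseless_series():
    """5-level tenfold series, E=1.9, no noise, fixed wells."""
    design = SimulationDesign(seed=11, n_replicates=3, noise_sd=0.0, f_m_cv=0.0,
                              baseline_a_range=(0.0, 0.0), baseline_b_range=(0.05, 0.05))
    return simulate_dilution_series(design)


@pytest.fixture
def noisy_replicates():
    """20 noisy replicates of one level (SD 0.3% of plateau)."""
    p = ModelParams(f_m=1.0, D=1.0, E=1.9, C_i=18.0, a=0.0002, b=0.05)
    rng = np.random.default_rng(20240111)
    return [
        simulate_curve(p, noise_sd=0.003, n_cycles=40, seed=rng, well_id=f"R{i}")
        for i in range(20)
    ]
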