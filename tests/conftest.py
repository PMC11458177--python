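import numpy as np
import pytest

import unfoldkin as uk


@pytest.fixture(scope="session")
def log_grid():
    """Coarse log-spaced grid spanning the stopped-flow acquisition window."""
    return np.geomspace(1e-2, 5000.0, 60)


@pytest.fixture(scope="session")
def reference_params():
    """Signal-model parameters in the regime of the 1:1 ATP:ATPgammaS fits."""
    return uk.SchemeParams(k_U=0.017, k_end=0.012, n=(362 - 93) / 56.5,
                           F1=1.0, F2=0.05)


@pytest.fixture(scope="session")
def small_noiseless_1to1():
    """Noiseless 1:1-condition dataset on a reduced grid (fast fits)."""
    design = uk.condition_1to1(
        seed=11, noise_sd=0.0, excluded_length=93.0, v_gammaS=0.0,
        dt1_values=(0.0,), n_replicates=1, n_points=600)
    return uk.simulate_dataset(design), design


@pytest.fixture(scope="session")
def small_noiseless_rel(small_noiseless_1to1):
    ds, _ = small_noiseless_1to1
    return [uk.relative_enhancement(tc) for tc in ds]
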