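import numpy as np
import pytest

from pegsolve import DesignConfig, QuantConfig, SimTruth, simulate_assay


@pytest.fixture
def design() -> DesignConfig:
    return DesignConfig()


@pytest.fixture
def quant() -> QuantConfig:
    return QuantConfig()


@pytest.fixture
def clean_sim(design, quant):
    """Noiseless simulated assay: exact forward model, no artifacts."""
    truth = SimTruth(
        peg_half_true=12.0, s_true=1.5, noise_sd=0.0, conc_noise_frac=0.0, seed=11
    )
    return simulate_assay(design, truth, quant), truth


@pytest.fixture
def noisy_sim(design, quant):
    """Simulated assay under the default study conditions (3% conc noise)."""
    truth = SimTruth(peg_half_true=12.0, s_true=1.5, seed=11)
    return simulate_assay(design, truth, quant), truth


@pytest.fixture
def wavelength_grid():
    return np.arange(220.0, 701.0)
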