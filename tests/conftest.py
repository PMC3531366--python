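import pytest

from betaglut import (
    PerturbationSpec,
    calibrate_full,
    calibrate_reduced,
)


@pytest.fixture(scope="session")
def calibrated():
    """Reduced-model maximum rates reconstructed from the printed anchors."""
    return calibrate_reduced()


@pytest.fixture(scope="session")
def params(calibrated):
    """Healthy reduced-model parameters (epsilon1 = epsilon2 = 1)."""
    return calibrated.to_reduced_params()


@pytest.fixture(scope="session")
def network(calibrated):
    """Fitted full regulatory model."""
    return calibrate_full(calibrated)


@pytest.fixture(scope="session")
def t2d(network):
    """The fitted T2D perturbation: nuclear exclusion of HNF1A/FOXA2."""
    return PerturbationSpec(nuclear_exclusion_factor=network.t2d_exclusion_factor)
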