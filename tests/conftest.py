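import pytest

from pelocore import (
    EnergyParams,
    build_pcar_core,
    build_ppro_core,
)
from pelocore.scenarios import calibrated_pcar_model


@pytest.fixture(scope="session")
def pcar():
    """P. carbinolicus core with default energy parameters."""
    return build_pcar_core(EnergyParams.pcar_defaults())


@pytest.fixture(scope="session")
def ppro():
    """P. propionicus core with default energy parameters."""
    return build_ppro_core(EnergyParams.ppro_defaults())


@pytest.fixture(scope="session")
def pcar_calibrated():
    """P. carbinolicus core after the one-shot biomass calibration."""
    with pytest.warns(UserWarning, match="calibration residual"):
        model, spec = calibrated_pcar_model()
    return model


@pytest.fixture()
def pcar_catabolic():
    """Zero-maintenance P. carbinolicus core for pure catabolic balances."""
    return build_pcar_core(EnergyParams(gam=97.5, ngam=0.0))


@pytest.fixture()
def ppro_catabolic():
    return build_ppro_core(EnergyParams(gam=97.5, ngam=0.0))
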