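import numpy as np
import pytest

from vegrot.soilwater import SoilLayer, SoilProfile, SoilWaterState


@pytest.fixture
def toy_profile() -> SoilProfile:
    """Three 10 cm layers with simple round-number limits."""
    mk = lambda top: SoilLayer(top=top, bottom=top + 10, bulk_density=1.3,
                               theta_s=0.45, theta_fc=0.30, theta_wp=0.10)
    return SoilProfile((mk(0), mk(10), mk(20)))


@pytest.fixture
def toy_state(toy_profile) -> SoilWaterState:
    return SoilWaterState(np.array([0.12, 0.20, 0.28]))
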