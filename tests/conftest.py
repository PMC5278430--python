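import numpy as np
import pytest

from echowing import AirProperties, Band, ChamberSpec

FS = 625_000.0


@pytest.fixture(scope="session")
def chamber() -> ChamberSpec:
    """Bench-top Perspex chamber: 20 cm cube (V=0.008 m^3, S~0.28 m^2
    including diffuser relief)."""
    return ChamberSpec(V=0.008, S=0.28)


@pytest.fixture(scope="session")
def air() -> AirProperties:
    return AirProperties()


@pytest.fixture(scope="session")
def band20k() -> Band:
    return Band.from_centre(20_000.0)


@pytest.fixture(scope="session")
def band40k() -> Band:
    return Band.from_centre(40_000.0)
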