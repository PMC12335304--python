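import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ssrflux import (
    CARVEDILOL,
    HPBCD,
    DiffusionCellConfig,
    PermeabilityDecomposition,
    default_membrane,
)

SAMPLING_5MIN = tuple(float(t) for t in range(0, 481, 5))


@pytest.fixture(scope="session")
def carvedilol():
    return CARVEDILOL


@pytest.fixture(scope="session")
def hpbcd():
    return HPBCD


@pytest.fixture()
def lipophilic_config():
    """Plain pH-10 buffer, 18 mL cells, 1.54 cm^2 lipophilic membrane."""
    return DiffusionCellConfig(
        V_donor=18.0,
        V_acceptor=18.0,
        membrane=default_membrane("lipophilic"),
        drug_dose_donor=20.0,
        solubility_donor=2.15,
        solubility_acceptor=2.15,
        sampling_times=SAMPLING_5MIN,
    )


@pytest.fixture()
def lipophilic_decomposition():
    """Stirred-cell barrier parameters: UWL ~ 350 um, fast neutral membrane."""
    return PermeabilityDecomposition(
        P_UWL=1.86e-4, P_membrane_u0=2.89e-4, f_0=0.994
    )
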