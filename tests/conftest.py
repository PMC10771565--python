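import numpy as np
import pytest

from mechanoscx import (Condition, ParameterSet, PressureProtocol,
                        default_parameters)
from mechanoscx.model import SPECIES, NetworkState

SP_IDX = {s: i for i, s in enumerate(SPECIES)}


@pytest.fixture(scope="session")
def defaults() -> ParameterSet:
    """The shipped calibrated parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def birth_death() -> ParameterSet:
    """Pure SCX birth-death subnetwork: production 50/h, decay 0.5/h,
    stationary mean 100 (every other rate zero)."""
    return ParameterSet(k_f0=0, k_fP=0, k_fd=0, k_y0=0, k_yM=0, k_yP=0,
                        k_yd=0, k_p0=0, k_pF=0, k_pd=0, k_e0=0, k_eY=0,
                        k_ed=0, k_s0=50.0, k_sE=0, k_sP=0, gamma_s=0.5,
                        delta_m=0.0)


@pytest.fixture(scope="session")
def decoupled(defaults) -> ParameterSet:
    """Defaults with every stimulus coupling removed: treatments become
    indistinguishable from control."""
    return defaults.replace(k_fP=0.0, k_yM=0.0, k_yP=0.0, k_sE=0.0,
                            k_sP=0.0, w_cross=0.0)


@pytest.fixture
def control() -> Condition:
    return Condition("control")


@pytest.fixture
def pressure_mgf() -> Condition:
    return Condition("pressure+MGF", 100, PressureProtocol(((0.0, 1.0, 120.0),)))


def make_state(**counts) -> NetworkState:
    """State with the four pools of 1000 and explicit overrides."""
    c = np.zeros(len(SPECIES), dtype=np.int64)
    for pool in ("FAK", "FYN", "ERK", "P38"):
        c[SP_IDX[f"{pool}_i"]] = 1000
    for name, v in counts.items():
        c[SP_IDX[name]] = v
        if name.endswith("_a"):
            c[SP_IDX[name.replace("_a", "_i")]] = 1000 - v
    return NetworkState(c)
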