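import numpy as np
import pytest

from cardiotwin import DoseEvent, PbpkModel
from cardiotwin.io import load_blocks
from cardiotwin.params import AbsorptionParams, CompoundParams, PhysiologySpec


@pytest.fixture(scope="session")
def model() -> PbpkModel:
    return PbpkModel.default()


@pytest.fixture(scope="session")
def blocks():
    return load_blocks()


@pytest.fixture(scope="session")
def single_dose_75():
    return [DoseEvent(time=0.0, dose_po=75.0)]


@pytest.fixture(scope="session")
def collapse_model() -> PbpkModel:
    """Single-compartment (lumped) configuration with unit partitioning:
    the closed-form first-order absorption/elimination oracle applies."""
    phys = PhysiologySpec(lumped=True, V_venous=50.0)
    parent = CompoundParams(name="AT", MW=277.4, Kp_ht=1.0, fu_ht=1.0, BP=1.0,
                            CL_other=10.0)
    met = CompoundParams(name="NT", MW=263.384, Kp_ht=1.0, fu_ht=1.0,
                         Kp_re=1.0, V_central=50.0, V_re=10.0, Q_re=10.0,
                         CL_other=5.0)
    ab = AbsorptionParams(ka=0.8, t_lag=0.0, F=0.5, fa_Fg=0.6)
    return PbpkModel(phys, parent, met, ab)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
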