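import numpy as np
import pytest

from levogut.params import DoseRegimen, KineticParameters, PhysiologyParameters
from levogut.pbpk import build_wb_acat
from levogut.network import add_levodopa_module, build_reduced_siec


@pytest.fixture(scope="session")
def physiology():
    return PhysiologyParameters()


@pytest.fixture(scope="session")
def kinetics():
    return KineticParameters()


@pytest.fixture(scope="session")
def model(physiology, kinetics):
    return build_wb_acat(physiology, kinetics)


@pytest.fixture(scope="session")
def single_dose_200():
    return DoseRegimen(events=((0.0, 200.0),), horizon=6.0)


@pytest.fixture(scope="session")
def q6h_100():
    return DoseRegimen.repeated(100.0, 6.0, 3, 18.0)


@pytest.fixture()
def siec_with_module():
    net = build_reduced_siec()
    add_levodopa_module(net)
    return net


@pytest.fixture(scope="session")
def siec_with_module_session():
    net = build_reduced_siec()
    add_levodopa_module(net)
    return net
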