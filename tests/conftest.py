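import numpy as np
import pytest

from cnspk.drug_params import DrugRecord, load_drugs
from cnspk.physiology import load_physiology, physiology_to_config
from cnspk.plasma_pk import DoseEvent, PlasmaModelSpec, load_plasma_models
from cnspk.workbench import default_physiology


@pytest.fixture(scope="session")
def rat_physiology():
    return default_physiology("rat")


@pytest.fixture(scope="session")
def human_physiology():
    return default_physiology("human")


@pytest.fixture(scope="session")
def drugs():
    return load_drugs()


@pytest.fixture(scope="session")
def plasma_models():
    return load_plasma_models()


@pytest.fixture
def rat_config(rat_physiology):
    """A mutable copy of the rat physiology config document."""
    return physiology_to_config(rat_physiology)


def make_drug(
    name="probe",
    mw=250.0,
    charge_class="neutral",
    pka=None,
    pkb=None,
    logp=1.0,
    kpuu=None,
    **kwargs,
):
    return DrugRecord(
        name=name,
        mw=mw,
        charge_class=charge_class,
        pka=pka,
        pkb=pkb,
        logp=logp,
        kpuu=kpuu if kpuu is not None else {"ecf": 0.5, "lv": 0.5, "cm": 0.5},
        **kwargs,
    )


@pytest.fixture
def neutral_drug():
    return make_drug()


@pytest.fixture
def simple_plasma_spec():
    """1-compartment IV spec without any variability."""
    return PlasmaModelSpec(
        name="test:simple", n_compartments=1, cl_cen=100.0, v_cen=10000.0
    )


@pytest.fixture
def bolus():
    return [DoseEvent(amount=1e6)]


@pytest.fixture
def time_grid():
    return np.arange(0.0, 481.0, 4.0)
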