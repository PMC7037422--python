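import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from radsynergy.conditions import NMType, SampleCondition
from radsynergy.cytometry import EventTable
from radsynergy.doseresponse import LL4Params
from radsynergy.synthdata import GenerativeParams


@pytest.fixture
def tio2_gp() -> GenerativeParams:
    """Standard uncoated-TiO2 72 h world, no interaction (null world)."""
    return GenerativeParams(
        nm_ll4=LL4Params(0.05, 0.85, 129.0, 1.3), ir_kill=0.255, synergy_coeff=0.0
    )


@pytest.fixture
def flat_mortality_gp() -> GenerativeParams:
    """Dose-independent 30% mortality, no irradiation effect."""
    return GenerativeParams(
        nm_ll4=LL4Params(0.3, 0.3, 10.0, 1.0), ir_kill=0.0, synergy_coeff=0.0
    )


def make_event_table(dioc, pi, ssc=None, fsc=None, sample_id="manual") -> EventTable:
    n = len(dioc)
    return EventTable(
        sample_id=sample_id,
        data=pd.DataFrame({
            "fsc": fsc if fsc is not None else np.full(n, 500.0),
            "ssc": ssc if ssc is not None else np.full(n, 100.0),
            "dioc": np.asarray(dioc, dtype=float),
            "pi": np.asarray(pi, dtype=float),
        }),
    )


@pytest.fixture
def ni_control_condition() -> SampleCondition:
    return SampleCondition(NMType.NONE, 0.0, False, timepoint_h=72.0)
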