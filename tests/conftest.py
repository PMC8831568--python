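import numpy as np
import pytest

from mearaster.mea_io import (
    N_ELECTRODES,
    ConditionLabel,
    SpikeTrain,
    WellRecording,
)


def make_recording(
    spikes_by_electrode=None,
    well_id="W00",
    duration_s=600.0,
    condition=None,
):
    """Build a WellRecording from a dict {electrode: [times]}; empty elsewhere."""
    spikes_by_electrode = spikes_by_electrode or {}
    condition = condition or ConditionLabel(
        compound="DMSO", concentration=0.1, concentration_unit="%v/v",
        is_vehicle=True, risk_class="seizure-free",
    )
    trains = []
    for e in range(N_ELECTRODES):
        times = np.asarray(sorted(spikes_by_electrode.get(e, [])), dtype=float)
        trains.append(SpikeTrain(e, times))
    return WellRecording(well_id, duration_s, tuple(trains), condition)


@pytest.fixture
def vehicle_condition():
    return ConditionLabel(
        compound="DMSO", concentration=0.1, concentration_unit="%v/v",
        is_vehicle=True, risk_class="seizure-free",
    )


@pytest.fixture
def drug_condition():
    return ConditionLabel(
        compound="testdrug", concentration=10.0, concentration_unit="uM",
        is_vehicle=False, risk_class="seizure-causing",
    )
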