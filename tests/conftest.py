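import numpy as np
import pytest

from thermocal import (
    CalibrationDataset,
    CalibrationRecord,
    SensorSimConfig,
    SplitSpec,
    simulate_blackbody_campaign,
    split_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_dataset():
    """12 records on a 4x3 (TBB, TC) grid with a known linear response."""
    records = []
    i = 0
    for tbb in (10.0, 25.0, 40.0, 55.0):
        for tc in (10.0, 20.0, 30.0):
            dl = 1000.0 + 80.0 * tbb - 5.0 * tc
            records.append(CalibrationRecord(f"r{i}", dl, tc, tbb))
            i += 1
    return CalibrationDataset(tuple(records))


@pytest.fixture
def split_campaign():
    """A default noisy campaign with a 65/35 stratified split."""
    ds = simulate_blackbody_campaign(SensorSimConfig(seed=7))
    return split_dataset(ds, SplitSpec(seed=7))
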