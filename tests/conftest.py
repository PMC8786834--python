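import numpy as np
import pytest

from hpmri import (
    AcquisitionSchedule,
    KineticParams,
    Lesion,
    Phantom,
    load_effect_config,
    simulate_dynamic_series,
)


@pytest.fixture(scope="session")
def schedule():
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def effect_config():
    return load_effect_config()


@pytest.fixture(scope="session")
def single_lesion_series():
    """Noiseless default-schedule series with one central kpl=0.015 lesion."""
    sch = AcquisitionSchedule()
    lesion = Lesion(center=(16, 16), radius=3.0, params=KineticParams(0.015, 0.0))
    phantom = Phantom(shape=sch.matrix, lesions=[lesion])
    return simulate_dynamic_series(phantom, sch)


def make_series(kpl, *, schedule=None, amplitude=1.0, rho_extra=0.0):
    sch = schedule or AcquisitionSchedule()
    lesion = Lesion(
        center=(sch.matrix[0] // 2, sch.matrix[1] // 2),
        radius=3.0,
        params=KineticParams(kpl, rho_extra),
        amplitude=amplitude,
    )
    return simulate_dynamic_series(Phantom(shape=sch.matrix, lesions=[lesion]), sch)


@pytest.fixture(scope="session")
def center_voxel_pair(single_lesion_series):
    from hpmri import TimeSeriesPair

    s = single_lesion_series
    return TimeSeriesPair(s.times, s.signal[16, 16, :, 0], s.signal[16, 16, :, 1])
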