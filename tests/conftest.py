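import numpy as np
import pytest

from dynapet.frames import FrameSchedule, parse_schedule_spec, STANDARD_SCHEDULES
from dynapet.phantom import IFParams, default_phantom, feng_if, region_masks


@pytest.fixture(scope="session")
def fdg_schedule():
    return parse_schedule_spec(STANDARD_SCHEDULES["fdg_60min"])


@pytest.fixture(scope="session")
def fgln_schedule():
    return parse_schedule_spec(STANDARD_SCHEDULES["fgln_30min"])


@pytest.fixture(scope="session")
def if_curve():
    """Default arterial input on the 1-s grid covering 60 min."""
    return feng_if(IFParams(), np.arange(0.0, 3601.0))


@pytest.fixture(scope="session")
def small_phantom():
    phantom, ifp, meta = default_phantom("small")
    return phantom


@pytest.fixture(scope="session")
def small_masks(small_phantom):
    return region_masks(small_phantom)


@pytest.fixture(scope="session")
def static_frame():
    """Noiseless late-uptake 10-min static frame of the small phantom."""
    from dynapet.phantom import render_dynamic

    phantom, ifp, _ = default_phantom("small")
    cp = feng_if(ifp, np.arange(0.0, 3601.0))
    schedule = FrameSchedule(((3000.0, 3600.0),))
    return render_dynamic(phantom, cp, schedule)
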