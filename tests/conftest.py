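import logging

import numpy as np
import pytest

import sleeppos as sp

logging.getLogger("sleeppos").setLevel(logging.ERROR)
logging.getLogger("sleeppos.position_summary").setLevel(logging.ERROR)


def make_series(sleep, stand=90.0, dt=0.1):
    """AngleSeries from a sleep-angle array (constant laying stand angle)."""
    sleep = np.asarray(sleep, dtype=float)
    stand_arr = np.full_like(sleep, float(stand)) if np.ndim(stand) == 0 else np.asarray(stand)
    t = np.arange(sleep.size) * dt
    return sp.AngleSeries(t=t, sleep_angle=sleep, stand_angle=stand_arr)


@pytest.fixture(scope="session")
def default_night():
    """One 2-hour untreated night from the default subject model."""
    return sp.simulate_night(sp.SubjectModel(), duration_hours=2.0, seed=11)


@pytest.fixture(scope="session")
def processed_night(default_night):
    """The same night pushed through the full orientation pipeline."""
    return sp.process_recording(default_night.accel)
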