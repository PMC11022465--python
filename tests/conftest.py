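import numpy as np
import pytest

from strollpipe.synthetic import (
    ActivityTimeline,
    Bout,
    CohortSpec,
    GaitTruth,
    generate_2mwt_signals,
    generate_cohort,
    generate_daily_recording,
)


@pytest.fixture(scope="session")
def walk_recording():
    """Standard noiseless-ish 2MWT: asymmetric gait at 0.8 m/s."""
    truth = GaitTruth(stride_time=1.2, gait_speed=0.8, asymmetry_ratio=1.2)
    rec, events = generate_2mwt_signals(truth, duration=120, rate=104,
                                        noise_sd=0.05, seed=7)
    return truth, rec, events


@pytest.fixture(scope="session")
def gait_day():
    """A 20-minute single-bout gait day at 1.0 m/s with moderate noise."""
    truth = GaitTruth(stride_time=1.2, gait_speed=1.0)
    tl = ActivityTimeline([Bout("gait", 1200, truth)])
    rec, day_truth = generate_daily_recording(tl, rate=52, noise_sd=0.3, seed=3)
    return truth, rec, day_truth


@pytest.fixture(scope="session")
def cohort_default():
    return generate_cohort(CohortSpec(seed=0))


def make_epoch(label=None, speed=None, rate=52.0, acc=None, gyr=None, start=0.0):
    """Minimal Epoch for bookkeeping-level tests."""
    from strollpipe.daily import EPOCH_S, Epoch

    n = int(EPOCH_S * rate)
    if acc is None:
        acc = np.tile([0.0, 0.0, 9.81], (n, 1))
    t = start + np.arange(acc.shape[0]) / rate
    return Epoch(start_time=start, t=t, acc=acc, gyr=gyr, rate=rate,
                 label=label, speed=speed)
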