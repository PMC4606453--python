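import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from larvasleep.io_tracking import ActivityMatrix, EpochSchedule

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150901)


@pytest.fixture
def schedule():
    """Standard 14 h:10 h LD schedule, lights on 9 am, experiment start 9 am."""
    return EpochSchedule()


def minute_matrix(values, start=0.0):
    """Helper: single- or multi-larva 60-s-binned ActivityMatrix from lists."""
    v = np.atleast_2d(np.asarray(values, dtype=float))
    return ActivityMatrix(
        larva_ids=tuple(f"L{i + 1:03d}" for i in range(v.shape[0])),
        bin_start_times=start + np.arange(v.shape[1]) * 60.0,
        bin_width=60.0,
        values=v,
    )
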