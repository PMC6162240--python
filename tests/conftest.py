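"""Shared fixtures: small deterministic layouts, schedules and recordings."""

import numpy as np
import pytest

from fearprobe import synth
from fearprobe.core import EpochSet


@pytest.fixture(scope="session")
def layout16():
    return synth.generate_sensor_layout(16, seed=0)


@pytest.fixture(scope="session")
def layout32():
    return synth.generate_sensor_layout(32, seed=0)


@pytest.fixture(scope="session")
def schedule():
    return synth.generate_trial_schedule(seed=7)


@pytest.fixture(scope="session")
def quiet_truth(layout16):
    """Low-noise ground truth: evoked components dominate."""
    return synth.default_ground_truth(
        layout16, background_amp_uV=0.5, cardiac_amp_uV=5.0, line_noise_amp_uV=2.0
    )


@pytest.fixture(scope="session")
def quiet_recording(schedule, layout16, quiet_truth):
    return synth.simulate_recording(schedule, layout16, quiet_truth, mode="tms", seed=3)


def make_epochs(data, fs_hz, layout, conditions=None, t0_ms=-500.0):
    """EpochSet wrapper around a raw (n_ep, n_ch, n_t) array."""
    n_ep, n_ch, n_t = data.shape
    times = t0_ms + np.arange(n_t) / fs_hz * 1000.0
    if conditions is None:
        conditions = ["T"] * n_ep
    return EpochSet(
        data=data,
        times_ms=times,
        conditions=np.asarray(conditions),
        us_paired=np.zeros(n_ep, dtype=bool),
        fs_hz=fs_hz,
        layout=layout,
    )
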