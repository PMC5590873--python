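import math

import numpy as np
import pytest

from hipfriction import (
    FRAME_HEAD_CENTER,
    FrameOffset,
    FrictionModelSpec,
    NoiseSpec,
    PendulumParams,
    WrenchSeries,
    generate_iso_waveforms,
    synthesize_wrench_series,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_pendulum():
    """Pendulum in the linearization regime: 5 degree release."""
    return PendulumParams(friction_torque=1.0,
                          initial_amplitude=math.radians(5.0))


@pytest.fixture
def head_center_series():
    """Helper building a head-center series from torque rows."""

    def make(torque_rows, rate=256.0, force_rows=None):
        m = np.atleast_2d(np.asarray(torque_rows, dtype=float))
        n = m.shape[0]
        f = (np.zeros((n, 3)) if force_rows is None
             else np.atleast_2d(np.asarray(force_rows, dtype=float)))
        return WrenchSeries(t=np.arange(n) / rate, force=f, torque=m,
                            frame=FRAME_HEAD_CENTER)

    return make


@pytest.fixture
def clean_iso_series():
    """Noise-free Coulomb walking-test record, 3 cycles at 1024 Hz."""
    gw = generate_iso_waveforms()
    return synthesize_wrench_series(
        gw,
        FrictionModelSpec(mu=0.09),
        FrameOffset(dz=0.15),
        NoiseSpec(torque_sd=0.0, force_sd=0.0, seed=0),
        n_cycles=3,
        rate=1024.0,
    )
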