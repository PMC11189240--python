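import numpy as np
import pytest

from lsoif import io as lsio
from lsoif.synaptic_inputs import (
    EXCITATORY,
    INHIBITORY,
    FiberDrive,
    conductance_trace,
    generate_fiber_train,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_drive_traces(
    exc_rate,
    inh_rate,
    duration,
    dt=0.002,
    seed=0,
    exc_vs=0.0,
    exc_fm=0.0,
    stream=(9, 0),
):
    """Conductance traces for a simple two-population Poisson drive."""
    rngs = lsio.fiber_rngs(seed, *stream)
    exc = [
        generate_fiber_train(
            FiberDrive(rate=exc_rate, vs=exc_vs, fm=exc_fm), duration, r
        )
        for name, r in rngs.items()
        if name.startswith("exc")
    ]
    inh = [
        generate_fiber_train(FiberDrive(rate=inh_rate), duration, r)
        for name, r in rngs.items()
        if name.startswith("inh")
    ]
    g_exc = conductance_trace(exc, EXCITATORY, dt, duration)
    g_inh = conductance_trace(inh, INHIBITORY, dt, duration)
    return g_exc, g_inh


@pytest.fixture
def drive_traces():
    return make_drive_traces
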