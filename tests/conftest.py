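import numpy as np
import pytest
from hypothesis import settings

from tcfit import SimConfig, SimulationResult, StimulusSpec, TCParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def default_params() -> TCParams:
    return TCParams()


@pytest.fixture
def square_spec() -> StimulusSpec:
    return StimulusSpec()


@pytest.fixture
def short_cfg() -> SimConfig:
    return SimConfig(dt=0.05, t_total=200.0, t_discard=0.0)


def make_trace_result(times, voltage, **kw) -> SimulationResult:
    """Build a SimulationResult carrying just a voltage trace."""
    times = np.asarray(times, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    z = np.zeros_like(times)
    return SimulationResult(
        times=times, voltage=voltage, h=z, r=z, applied_current=z, **kw
    )


@pytest.fixture
def triangle_trace():
    """Voltage trace with three triangular excursions above -25 mV whose
    apices sit at known times, on a baseline of -65 mV."""
    dt = 0.1
    times = np.arange(0.0, 100.0, dt)
    v = np.full_like(times, -65.0)
    apices = [20.0, 50.0, 80.0]
    for apex in apices:
        tri = 10.0 - 8.0 * np.abs(times - apex)  # peak 10 mV, width 10 ms
        v = np.maximum(v, tri)
    return make_trace_result(times, v), apices
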