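import dataclasses

import numpy as np
import pytest

import dissipel as dl

# canonical steady-pipe study conditions: blood properties, R = 2 mm,
# L = 20 mm, mean velocity 0.3 m/s
PIPE_R = 2e-3
PIPE_L = 2e-2
VBAR = 0.3


@pytest.fixture(scope="session")
def props():
    return dl.BLOOD


@pytest.fixture(scope="session")
def pipe16():
    return dl.make_pipe_mesh(PIPE_R, PIPE_L, 16)


@pytest.fixture(scope="session")
def pipe24():
    """Default validation mesh for oracle-equivalence checks."""
    return dl.make_pipe_mesh(PIPE_R, PIPE_L, 24)


@pytest.fixture(scope="session")
def poiseuille24(pipe24):
    return dl.poiseuille_snapshot(pipe24, VBAR)


@pytest.fixture(scope="session")
def pipe24_dp(pipe24, poiseuille24, props):
    grad = dl.gradient_unstructured(pipe24, poiseuille24)
    return dl.dissipation_power(dl.dissipation_function(grad, props))


@pytest.fixture(scope="session")
def pipe24_sections(pipe24, poiseuille24, props):
    """Steady inlet/outlet summaries replicated at t = 0 and t = period."""
    interp = dl.FieldInterpolator(pipe24)
    out = {}
    for name, x in (("inlet", 0.0), ("outlet", PIPE_L)):
        sect = dl.make_disk_section((x, 0, 0), (1, 0, 0), PIPE_R, 24)
        s = dl.cross_section_summary(sect, poiseuille24, props, interp)
        out[name] = [dataclasses.replace(s, time=0.0), dataclasses.replace(s, time=0.8)]
    return out


@pytest.fixture(scope="session")
def aneurysm16():
    return dl.idealized_aneurysm_fixture(resolution=16, seed=0)


@pytest.fixture(scope="session")
def small_box():
    return dl.make_box_mesh((0.01, 0.001, 0.005), (9, 7, 7))


def steady_power_series(dp_value, period=0.8, n_steps=2, n_cycles=1):
    t = np.linspace(0, n_cycles * period, n_cycles * n_steps + 1)
    return dl.PowerSeries(t, np.full_like(t, dp_value))
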