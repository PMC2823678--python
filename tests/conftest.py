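"""Shared simulation fixtures (session-scoped: these are the expensive runs).

All acceptance-grade runs use the coarse Δx = 50 μm tier; shear grids sit
inside the model's flow-resistance window (see docs/methods.md on the
compressed shear scale of the reconstructed constant set).
"""

import numpy as np
import pytest

import clotflow as cf
from clotflow.experiments import make_scenario, run_sweep
from clotflow.metrics import LagtimeCurve
from clotflow.transport import IntegratorConfig

DX = 50.0
CONTROL_SHEARS = (0.0, 1.0, 2.0)
ENZYME_OFF_SHEARS = (0.0, 14.0)


def coarse(preset, shears, end_min, **ikw):
    return make_scenario(
        preset,
        domain=cf.DomainSpec(dx=DX),
        gamma_w=tuple(shears),
        integrator=IntegratorConfig(end_time=end_min * 60.0, **ikw),
    )


@pytest.fixture(scope="session")
def control_curve():
    """Control lagtime curve over the resistance window {0, 1, 2} s⁻¹."""
    return run_sweep(coarse("control", CONTROL_SHEARS, 25.0))


@pytest.fixture(scope="session")
def enzymes_off_curve():
    """Lagtime curve with convection disabled for every enzyme."""
    lags = []
    for g in ENZYME_OFF_SHEARS:
        scen = coarse("no_convection_enzymes", (g,), 20.0)
        lags.append(cf.run_simulation(scen, g).lagtime_min)
    return LagtimeCurve(np.array(ENZYME_OFF_SHEARS), np.array(lags), "no_convection_enzymes")


@pytest.fixture(scope="session")
def enzymes_off_window_lags(control_curve):
    """Enzymes-off lagtimes on the control sweep grid (for the
    flow-influence ratio)."""
    lags = []
    for g in CONTROL_SHEARS:
        scen = coarse("no_convection_enzymes", (g,), 25.0)
        lags.append(cf.run_simulation(scen, g).lagtime_min)
    return LagtimeCurve(np.array(CONTROL_SHEARS), np.array(lags), "no_convection_enzymes")


@pytest.fixture(scope="session")
def stagnant_24min():
    """Control run in stagnant plasma carried to 24 simulated minutes."""
    scen = coarse("control", (0.0,), 24.2, run_to_end=True)
    return cf.run_simulation(scen, 0.0)
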