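"""Shared fixtures: coarse solver settings and a cached mini-sweep."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leukotransit.fsi_sim import SimulationParams, run_transit

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def coarse_params(Re, AR, **kw):
    """Quick desk-scale solver settings used throughout the suite."""
    defaults = dict(grid_cells_per_diameter=8, max_sim_time=0.25, output_interval=2e-4)
    defaults.update(kw)
    return SimulationParams(Re=Re, AR=AR, **defaults)


@pytest.fixture(scope="session")
def baseline_transit():
    """One completed coarse transit at the baseline scenario (Re 0.1, AR 0.8)."""
    return run_transit(coarse_params(0.1, 0.8))


@pytest.fixture(scope="session")
def fast_transit():
    """A very coarse, very fast transit (wide pore) for smoke checks."""
    return run_transit(coarse_params(0.15, 1.2, grid_cells_per_diameter=6))
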