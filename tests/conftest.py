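"""Shared fixtures: small solved networks and short synthetic loops."""

from __future__ import annotations

import numpy as np
import pytest

from ulm2d.simulate import SequenceConfig, generate_sequence
from ulm2d.simulate.network import VesselNetwork, solve_flow


def straight_tube(radius_um: float = 50.0, length_um: float = 1000.0,
                  origin=(500.0, 500.0)) -> VesselNetwork:
    """A single horizontal vessel segment with inlet left, outlet right."""
    x0, y0 = origin
    nodes = np.array([[x0, y0], [x0 + length_um, y0]])
    return VesselNetwork(
        node_xy_um=nodes,
        seg_nodes=np.array([[0, 1]]),
        radius_um=np.array([radius_um]),
        boundary_nodes=np.array([0, 1]),
        boundary_pressure_pa=np.array([1.0, 0.0]),
    )


@pytest.fixture(scope="session")
def short_loop():
    """A 20-frame full-density synthetic loop with ground truth."""
    cfg = SequenceConfig(duration_s=2.0, seed=7)
    return generate_sequence(cfg)


@pytest.fixture(scope="session")
def single_mb_loop():
    """A 30-frame loop containing only well-separated single echoes."""
    cfg = SequenceConfig(duration_s=3.0, seed=11, single_mb_only=True)
    return generate_sequence(cfg)


@pytest.fixture()
def solved_tube():
    return solve_flow(straight_tube(), pressure_drop_pa=1.0,
                      viscosity_pa_s=1.0)
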