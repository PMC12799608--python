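"""Shared fixtures: canonical geometries, trajectories and tiny datasets."""

import numpy as np
import pytest

from cellmech.mechanics import IndentationTrajectory, PLRParameters, TipGeometry


@pytest.fixture
def micron_tip() -> TipGeometry:
    """1 um spherical tip, incompressible sample — the closed-form setting."""
    return TipGeometry(radius=1e-6, poisson_ratio=0.5)


@pytest.fixture
def soft_probe() -> TipGeometry:
    """Default live-cell probe: R = 70 nm, k = 0.1 N/m, nu = 0.5."""
    return TipGeometry()


def triangular_trajectory(tm: float = 1.0, speed: float = 1e-6,
                          n: int = 257) -> IndentationTrajectory:
    """Symmetric constant-rate approach/retract ramp reaching speed*tm."""
    t = np.linspace(0.0, 2.0 * tm, 2 * n - 1)
    d = np.where(t <= tm, speed * t, np.clip(speed * (2 * tm - t), 0.0, None))
    return IndentationTrajectory(time=t, indentation=d, t_approach=tm)


@pytest.fixture
def ramp_trajectory() -> IndentationTrajectory:
    return triangular_trajectory()


@pytest.fixture
def plr_solid() -> PLRParameters:
    return PLRParameters(E0=1000.0, alpha=0.0, eta=0.0)
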