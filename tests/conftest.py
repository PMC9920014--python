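"""Shared fixtures: small phantoms and cheap acquisition settings."""

from __future__ import annotations

import numpy as np
import pytest

from axmwi.fdtd import SimConfig
from axmwi.phantom import ALNSpec, Phantom, PhantomConfig
from axmwi.pulse import PulseSpec


def blank_phantom(n_rows: int, n_cols: int, dx_mm: float = 0.5, air_gap_mm: float = 0.0) -> Phantom:
    """Homogeneous vacuum phantom for solver-level tests."""
    shape = (n_rows, n_cols)
    return Phantom(
        tissue=np.zeros(shape, np.int8),
        eps_inf=np.ones(shape),
        delta_eps=np.zeros(shape),
        sigma_s=np.zeros(shape),
        tau=np.full(shape, 13e-12),
        dx_mm=dx_mm,
        air_gap_mm=air_gap_mm,
        antenna_xy_mm=np.zeros((0, 2)),
        antenna_cells=np.zeros((0, 2), dtype=int),
        truths=[],
        config=None,
    )


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Desk-scale phantom: 60 mm wide, 40 mm deep, 6 antennas over 40 mm."""
    return PhantomConfig(
        depth_mm=40.0,
        width_mm=60.0,
        alns=(ALNSpec(depth_mm=15.0, long_axis_mm=8.0),),
        n_antennas=6,
        span_mm=40.0,
    )


@pytest.fixture(scope="session")
def fast_sim() -> SimConfig:
    return SimConfig(time_window=1.5e-9)


@pytest.fixture(scope="session")
def pulse() -> PulseSpec:
    return PulseSpec()
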