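"""Shared fixtures and independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from phycogradients.phycosphere import CellParams, MediumParams
from phycogradients.plate import (AlgalPopulation, Edge, PlateLayout, Reservoir,
                                  WallParams, Well, WellRole, build_layout)
from phycogradients.units import FMOL_PER_DAY_TO_MOL_PER_S, MOL_PER_M3_TO_UM, UM_TO_M


def fd_steady_profile(rate_fmol_per_day: float, d: float, r_grid_um: np.ndarray,
                      bulk_um: float, sink: bool = False) -> np.ndarray:
    """Finite-difference steady state of spherical diffusion, independent
    of the closed-form implementation.

    Solves d/dr(r^2 dC/dr) = 0 in conservation form on the given log
    grid with a prescribed total flux through the cell surface (source
    or sink) and a Dirichlet far-field value anchoring the offset at the
    outer grid point.  Returns concentrations in µM.
    """
    r = np.asarray(r_grid_um, dtype=float) * UM_TO_M
    n = r.size
    q_si = rate_fmol_per_day * FMOL_PER_DAY_TO_MOL_PER_S * (-1.0 if sink else 1.0)
    # interface positions and conductances g_i+1/2 = 4*pi*D*r_f^2/dr
    r_face = np.sqrt(r[:-1] * r[1:])
    g = 4.0 * np.pi * d * r_face ** 2 / np.diff(r)
    a = np.zeros((n, n))
    b = np.zeros(n)
    # interior conservation: flux in = flux out
    for i in range(1, n - 1):
        a[i, i - 1] = g[i - 1]
        a[i, i] = -(g[i - 1] + g[i])
        a[i, i + 1] = g[i]
    # inner boundary: total release Q crosses the first interface
    # (the system is assembled with C in µM, so the molar flux is
    # converted to match: g * C[µM] has units mol/s * 1e3)
    a[0, 0], a[0, 1] = -g[0], g[0]
    b[0] = -q_si * MOL_PER_M3_TO_UM
    # outer boundary: far-field value of the same BVP (anchors the offset;
    # the interior shape is determined by the FD conservation equations)
    a[-1, -1] = 1.0
    b[-1] = bulk_um + q_si / (4.0 * np.pi * d * r[-1]) * MOL_PER_M3_TO_UM
    c = np.linalg.solve(a, b)
    return c


@pytest.fixture
def small_cell() -> CellParams:
    return CellParams("testcell", radius_um=2.0, exudation_q=50.0,
                      uptake_vmax=20.0, uptake_km=1.5)


@pytest.fixture
def medium() -> MediumParams:
    return MediumParams(bulk_doc=0.01, bulk_nitrate=882.0)


@pytest.fixture
def two_well_layout() -> PlateLayout:
    """Two equal wells joined by one wall, no reservoir edge."""
    wall = WallParams()
    wells = [Well("a", 0.0, 0.0, 100.0, WellRole.alga),
             Well("b", 8.0, 0.0, 100.0, WellRole.bacteria)]
    return PlateLayout(wells, [Edge("a", "b", wall)], Reservoir(), name="pair")


@pytest.fixture
def community_series():
    """Default 7-day community-layout nutrient run (alga only), shared
    across tests to keep the suite fast."""
    from phycogradients.plate import simulate_plate
    layout = build_layout("community_layers")
    return simulate_plate(layout, AlgalPopulation(), t_span=(0.0, 7.0),
                          dt_out=0.05)
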