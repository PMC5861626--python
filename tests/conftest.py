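"""Shared fixtures: the expensive solver runs are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bridgeflow import (
    BoundaryConditions,
    FluidProperties,
    RunConfig,
    SolverConfig,
    WallLabel,
    average_wss,
    build_channel,
    build_geometry,
    rasterize,
    solve_steady,
    wall_shear_profile,
)
from bridgeflow.sweep import reference_subset, run_sweep

BLOOD = FluidProperties()  # 1050 kg/m^3, 4.24e-3 Pa s


@pytest.fixture(scope="session")
def channel_case():
    """Plane-Poiseuille validation channel: 8 mm wide, parabolic inlet at 0.15 m/s."""
    geo = build_channel(width=8.0, length=32.0)
    mask = rasterize(geo, 0.25)
    bc = BoundaryConditions(u_ss_inlet=0.15, u_bv_inlet=0.0, inlet_profile="parabolic")
    field = solve_steady(mask, bc, BLOOD, SolverConfig())
    return geo, field


@pytest.fixture(scope="session")
def junction_case():
    """Desk-scale junction: 2 mm vein entering at 43 deg against the stream."""
    geo = build_geometry(8.0, 2.0, 43.0, (14.0, 28.0, 16.0))
    mask = rasterize(geo, 0.25)
    field = solve_steady(mask, BoundaryConditions(), BLOOD,
                         SolverConfig(max_iterations=70_000))
    return geo, field


@pytest.fixture(scope="session")
def convergence_errors():
    """Relative wall-shear errors of the Poiseuille channel at three resolutions.

    Diffusive scaling with the slip-free bounce-back relaxation
    tau = 1/2 + sqrt(3/16), so the error sequence isolates the scheme's
    spatial order.
    """
    U, H, L = 0.01, 2.0, 8.0
    exact = 6 * BLOOD.viscosity * U / (H * 1e-3)
    magic_tau = 0.5 + np.sqrt(3.0 / 16.0)
    errors = []
    for h, check in ((0.2, 1000), (0.1, 4000), (0.05, 16000)):
        geo = build_channel(H, L)
        mask = rasterize(geo, h)
        bc = BoundaryConditions(u_ss_inlet=U, u_bv_inlet=0.0, inlet_profile="parabolic")
        cfg = SolverConfig(relaxation_time=float(magic_tau), tolerance=1e-10,
                           check_every=check, ramp_steps=500, avg_steps=0,
                           max_iterations=600_000)
        field = solve_steady(mask, bc, BLOOD, cfg)
        prof = wall_shear_profile(field, geo.walls[WallLabel.SSD])
        tau_w = average_wss(prof, (L * 0.3, L * 0.7))
        errors.append(abs(tau_w - exact) / exact)
    return errors


@pytest.fixture(scope="session")
def mirror_fields():
    """The 90-degree junction solved on the mask and on its x-mirror."""
    geo = build_geometry(8.0, 2.0, 90.0, (10.0, 10.0, 6.0))
    mask = rasterize(geo, 0.25)
    cfg = SolverConfig(max_iterations=20_000, avg_steps=0)
    f1 = solve_steady(mask, BoundaryConditions(), BLOOD, cfg)
    f2 = solve_steady(mask.mirror_x(), BoundaryConditions(), BLOOD, cfg)
    return f1, f2


@pytest.fixture(scope="session")
def subset_sweep():
    """The stratified 12-model reference sweep at the desk-scale profile."""
    return run_sweep(reference_subset(), RunConfig.desk_scale(), progress=False)
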