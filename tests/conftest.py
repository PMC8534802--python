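"""Shared fixtures: small meshes, blood models, and the factorial run.

The full 8-case factorial is expensive, so it runs once per session and
is shared by every test that audits its report (conservation, cycle
convergence, directional findings).
"""

from __future__ import annotations

import numpy as np
import pytest

from aortoflow.geometry import Outlet, VesselGeometry
from aortoflow.meshing import mesh_geometry
from aortoflow.rheology import BloodProperties

#: constant-viscosity blood used by the channel benchmarks (mu = 3.5 mPa*s)
CHANNEL_MU = 3.5e-3
CHANNEL_H = 0.02
CHANNEL_L = 0.1


def channel_geometry(length: float = CHANNEL_L, width: float = CHANNEL_H) -> VesselGeometry:
    """Plane channel with a single distal outlet (Poiseuille benchmark)."""
    return VesselGeometry(
        length=length,
        width=width,
        outlets=(Outlet("out", "distal", length, width),),
    )


@pytest.fixture(scope="session")
def newtonian_blood() -> BloodProperties:
    return BloodProperties(mu_p=CHANNEL_MU, hct=0.0)


@pytest.fixture(scope="session")
def channel_mesh():
    return mesh_geometry(channel_geometry(), bulk_size=2e-3, first_layer=1e-4)


@pytest.fixture(scope="session")
def poiseuille(channel_mesh, newtonian_blood):
    """Converged steady Poiseuille flow at Re ~ 100 on the default mesh."""
    from aortoflow.solver import ProjectionSolver

    rho = newtonian_blood.rho
    u_mean = 100.0 * CHANNEL_MU / (rho * CHANNEL_H)
    solver = ProjectionSolver.steady(
        channel_mesh, newtonian_blood, u_mean, profile="parabolic"
    )
    field = solver.solve_steady()
    return {
        "field": field,
        "solver": solver,
        "mesh": channel_mesh,
        "props": newtonian_blood,
        "u_mean": u_mean,
    }


@pytest.fixture(scope="session")
def factorial(tmp_path_factory):
    """The full 8-case factorial experiment (5 cycles, discard 3)."""
    from aortoflow.pipeline import run_experiment

    outdir = tmp_path_factory.mktemp("factorial")
    report = run_experiment(outdir, seed=0)
    assert report["complete"], report
    return report
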