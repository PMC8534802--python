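"""Projection solver: fixed points, conservation, protocol bookkeeping."""

import numpy as np
import pytest

from aortoflow import operators, post
from aortoflow.meshing import mesh_geometry
from aortoflow.rheology import BloodProperties
from aortoflow.solver import (
    BoundaryConditions,
    ProjectionSolver,
    StepSizeError,
    check_laminar,
    step,
)
from aortoflow.synthetic import generate_inlet_waveform
from tests.conftest import CHANNEL_H, CHANNEL_MU, channel_geometry


@pytest.fixture(scope="module")
def small_mesh():
    return mesh_geometry(
        channel_geometry(length=0.04, width=0.012), bulk_size=2e-3, first_layer=2e-4
    )


def test_rest_state_is_fixed_point(small_mesh):
    """Zero inlet, zero field, zero gauge pressure: nothing moves."""
    props = BloodProperties(hct=0.0)
    solver = ProjectionSolver(small_mesh, props, BoundaryConditions(inlet=0.0))
    for _ in range(5):
        f = solver.step(1e-3)
    assert np.abs(f.u).max() == 0.0
    assert np.abs(f.v).max() == 0.0
    assert np.abs(f.p).max() == 0.0


def test_poiseuille_centerline_and_conservation(poiseuille):
    """Steady Re~100 channel flow: parabolic profile and mass balance."""
    field, solver, mesh = poiseuille["field"], poiseuille["solver"], poiseuille["mesh"]
    u_mean = poiseuille["u_mean"]
    assert post.centerline_velocity(field, mesh) == pytest.approx(
        1.5 * u_mean, rel=0.02
    )
    q_in = solver.inlet_flow()
    q_out = sum(solver.outlet_flows().values())
    assert abs(q_out - q_in) / q_in <= 5e-3
    assert solver.last_max_rel_div <= 1e-8


def test_poiseuille_wall_shear_stress(poiseuille):
    field, mesh, props = poiseuille["field"], poiseuille["mesh"], poiseuille["props"]
    analytic = 6.0 * CHANNEL_MU * poiseuille["u_mean"] / CHANNEL_H
    for wall in ("wall:bottom", "wall:top"):
        prof = post.wss_profile(field, mesh, wall, props)
        mid = prof.wss[prof.arc_coordinate > 0.05]
        assert mid.mean() == pytest.approx(analytic, rel=0.03)


def test_no_slip_walls_by_construction(poiseuille):
    field, mesh = poiseuille["field"], poiseuille["mesh"]
    assert np.abs(field.v[:, 0]).max() <= 1e-10
    assert np.abs(field.v[:, -1]).max() <= 1e-10


def test_cfl_violation_raises_step_size_error(small_mesh):
    props = BloodProperties(hct=0.0)
    solver = ProjectionSolver(small_mesh, props, BoundaryConditions(inlet=0.0))
    solver.u[:, :] = 10.0  # 10 m/s across 2 mm cells
    with pytest.raises(StepSizeError, match="CFL"):
        solver.step(1e-3)


def test_newtonian_limit_matches_constant_viscosity(small_mesh):
    """k0 = k_inf reproduces the constant-viscosity solver exactly."""
    shear_thinning_off = BloodProperties(k0=2.07, k_inf=2.07, hct=0.40)
    mu_const = float(
        shear_thinning_off.mu_p
        * (1.0 - 2.07 * shear_thinning_off.hct_factor()) ** -2
    )
    plain = BloodProperties(mu_p=mu_const, hct=0.0)
    wf = generate_inlet_waveform("real", 0.05, period=0.2)
    fields = []
    for props in (shear_thinning_off, plain):
        solver = ProjectionSolver(small_mesh, props, BoundaryConditions(inlet=wf))
        for _ in range(40):
            f = solver.step(1e-3)
        fields.append(f)
    scale = np.abs(fields[0].u).max()
    assert np.abs(fields[0].u - fields[1].u).max() <= 1e-6 * scale
    assert np.abs(fields[0].v - fields[1].v).max() <= 1e-6 * scale


def test_divergence_free_after_every_projection(small_mesh):
    props = BloodProperties(hct=0.40)
    wf = generate_inlet_waveform("real", 0.05, period=0.2)
    solver = ProjectionSolver(small_mesh, props, BoundaryConditions(inlet=wf))
    for _ in range(30):
        solver.step(1e-3)
        assert solver.last_max_rel_div <= 1e-8
        assert solver.last_mass_imbalance <= 5e-3


def test_run_cycles_retention_bookkeeping(small_mesh):
    """With discard = 3 of 4 cycles, snapshots span only the last cycle."""
    props = BloodProperties(hct=0.0)
    wf = generate_inlet_waveform("real", 0.05, period=0.1)
    solver = ProjectionSolver(small_mesh, props, BoundaryConditions(inlet=wf))
    series = solver.run_cycles(4, discard=3, steps_per_cycle=100, snapshots_per_cycle=10)
    times = np.array([f.t for f in series.fields])
    assert times.min() > 3 * 0.1
    assert times.max() <= 4 * 0.1 + 1e-12
    assert len(series.fields) == 10
    # phase-addressable snapshots: any in-cycle display time can be requested
    snap = series.at_phase(0.18)
    assert abs((snap.t / 0.1) % 1.0 - 0.18) < 0.06


def test_steady_inlet_cycles_converge_immediately(small_mesh):
    """A constant inlet makes successive cycles identical once the viscous
    start-up transient has died (high viscosity keeps that within a cycle)."""
    props = BloodProperties(mu_p=0.3, hct=0.0)
    flat = generate_inlet_waveform("real", 0.03, period=0.1, peak_to_mean=1.0001)
    solver = ProjectionSolver(small_mesh, props, BoundaryConditions(inlet=flat))
    series = solver.run_cycles(4, discard=1, steps_per_cycle=50)
    assert series.cycle_metrics[-1] < 5e-3
    assert series.cycle_metrics[-1] < series.cycle_metrics[0]


def test_module_level_step_round_trip(small_mesh):
    props = BloodProperties(hct=0.0)
    bc = BoundaryConditions(inlet=0.02)
    solver = ProjectionSolver(small_mesh, props, bc)
    f1 = solver.step(1e-3)
    solver2 = ProjectionSolver(small_mesh, props, bc)
    f0 = solver2.state()
    f1b = step(f0, 1e-3, small_mesh, bc, props)
    assert np.allclose(f1.u, f1b.u, atol=1e-15)


class TestCheckLaminar:
    def _series(self, q_in, props, mesh):
        from aortoflow.solver import CycleSeries

        log = {
            "t": [0.0],
            "inlet_flow": [q_in],
            "outlet_flows": [{"out": q_in}],
            "max_rel_div": [0.0],
            "mass_imbalance": [0.0],
        }
        return CycleSeries(
            fields=[], cycle_metrics=[], dt=1e-3, period=1.0, discard=3,
            peak_velocity=0.0, log=log, mesh=mesh, props=props, bc=None,
        )

    def test_direct_arithmetic(self, channel_mesh):
        from aortoflow.rheology import viscosity_field

        props = BloodProperties(mu_p=3.5e-3, hct=0.0)
        series = self._series(0.3 * CHANNEL_H, props, channel_mesh)
        rep = check_laminar(series)
        # rho U D / mu with U = 0.3, D = 0.02, mu = 3.5 mPa s -> Re ~ 1783
        assert rep["inlet"]["Re"] == pytest.approx(1040 * 0.3 * 0.02 / 3.5e-3, rel=1e-12)
        assert rep["inlet"]["laminar"] and rep["all_laminar"]

    def test_zero_velocity_limit(self, channel_mesh):
        props = BloodProperties(hct=0.0)
        rep = check_laminar(self._series(0.0, props, channel_mesh))
        assert rep["inlet"]["Re"] == 0.0

    def test_doubling_viscosity_halves_re(self, channel_mesh):
        r1 = check_laminar(
            self._series(0.3 * CHANNEL_H, BloodProperties(mu_p=3.5e-3, hct=0.0), channel_mesh)
        )
        r2 = check_laminar(
            self._series(0.3 * CHANNEL_H, BloodProperties(mu_p=7.0e-3, hct=0.0), channel_mesh)
        )
        assert r1["inlet"]["Re"] == pytest.approx(2.0 * r2["inlet"]["Re"], rel=1e-12)

    def test_turbulent_flow_flagged(self, channel_mesh):
        props = BloodProperties(mu_p=3.5e-3, hct=0.0)
        rep = check_laminar(self._series(1.0 * CHANNEL_H, props, channel_mesh))
        assert not rep["inlet"]["laminar"]
        assert not rep["all_laminar"]
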