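"""Vessel geometry construction, graded meshing, STL export."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortoflow.geometry import (
    Flap,
    Outlet,
    Tear,
    VesselGeometry,
    build_geometry,
)
from aortoflow.meshing import (
    MeshingError,
    _graded_band,
    export_stl,
    mesh_geometry,
    mesh_independence,
)


class TestBuildGeometry:
    def test_control_case_has_no_internal_walls(self):
        geom = build_geometry(False)
        assert not geom.dissected
        mesh = mesh_geometry(geom)
        assert mesh.fluid.all()

    def test_half_offset_flap_splits_width(self):
        geom = build_geometry(True)
        y_lo, y_hi = geom.flap_y_interval()
        assert 0.5 * (y_lo + y_hi) == pytest.approx(0.5 * geom.width)

    def test_lumens_connected_only_through_tears_and_distal_end(self):
        from scipy import ndimage

        mesh = mesh_geometry(build_geometry(True))
        labels, n = ndimage.label(mesh.fluid)
        assert n == 1  # one connected fluid region
        # sealing all tears isolates the false lumen
        params = {"tears": ()}
        with pytest.raises(ValueError):
            build_geometry(True, params)

    def test_boundary_closure_audit(self):
        """Inlet + outlets + walls tile every open boundary face exactly once."""
        mesh = mesh_geometry(build_geometry(True))
        tags = mesh.boundary_tags()
        outlet_names = {t.split(":", 1)[1] for t in tags.values() if t.startswith("outlet")}
        assert len(outlet_names) >= 2
        n_boundary = (
            int(mesh.fluid[0, :].sum())
            + int(mesh.fluid[-1, :].sum())
            + int(mesh.fluid[:, 0].sum())
            + int(mesh.fluid[:, -1].sum())
        )
        outer = [k for k in tags if not tags[k].startswith("wall:flap")]
        assert len(outer) == n_boundary
        assert all(
            t == "inlet" or t == "wall" or t.startswith("outlet") or t == "wall:flap"
            for t in tags.values()
        )

    def test_tear_outside_flap_rejected(self):
        with pytest.raises(ValueError):
            VesselGeometry(
                length=0.1,
                width=0.02,
                outlets=(Outlet("o", "distal", 0.1, 0.02),),
                flap=Flap(0.02, 0.06, 0.001, tears=(Tear(0.08, 0.005),)),
            )


class TestMeshGrading:
    def test_boundary_layer_depth_geometric_sum(self):
        """0.1 mm first layer, ratio 1.15, 5 layers -> 0.674 mm depth."""
        mesh = mesh_geometry(
            build_geometry(False), bulk_size=2e-3, first_layer=1e-4, ratio=1.15,
            n_boundary_layers=5,
        )
        depth = mesh.boundary_layer_heights().sum()
        assert depth == pytest.approx(1e-4 * (1.15**5 - 1) / 0.15, rel=1e-12)
        assert depth == pytest.approx(0.674e-3, rel=1e-3)

    def test_layer_sequence_exactly_geometric(self):
        mesh = mesh_geometry(build_geometry(True), first_layer=1e-4, ratio=1.15)
        h = mesh.boundary_layer_heights()
        assert h[0] == pytest.approx(1e-4, rel=1e-12)
        assert np.allclose(h[1:] / h[:-1], 1.15, rtol=1e-12)

    def test_unity_ratio_gives_uniform_layers(self):
        mesh = mesh_geometry(
            build_geometry(False), bulk_size=2e-3, first_layer=5e-4, ratio=1.0,
            n_boundary_layers=3,
        )
        h = mesh.boundary_layer_heights()
        assert np.allclose(h, 5e-4)

    def test_cell_areas_tessellate_fluid_region(self):
        for dissected in (False, True):
            geom = build_geometry(dissected)
            mesh = mesh_geometry(geom)
            filled = mesh.cell_areas()[mesh.fluid].sum()
            solid_area = 0.0
            if dissected:
                y_lo, y_hi = geom.flap_y_interval()
                th = y_hi - y_lo
                solid_area = sum(x1 - x0 for x0, x1 in geom.flap.segments()) * th
                solid_area += geom.flap.thickness * (geom.width - y_hi)  # cap
            expected = geom.length * geom.width - solid_area
            assert filled == pytest.approx(expected, rel=1e-6)

    def test_too_narrow_band_raises_diagnostic(self):
        with pytest.raises(MeshingError, match="narrow"):
            _graded_band(4e-4, 1e-4, 1.15, 2e-3, 5)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        dissected=st.booleans(),
        bulk=st.floats(1.5e-3, 4e-3),
        first=st.floats(5e-5, 4e-4),
        ratio=st.floats(1.0, 1.4),
    )
    def test_fuzzed_meshes_are_solver_ready(self, dissected, bulk, first, ratio):
        """Every mesh the builder emits is valid input to the flow solver."""
        from aortoflow.rheology import BloodProperties
        from aortoflow.solver import ProjectionSolver

        mesh = mesh_geometry(
            build_geometry(dissected), bulk_size=bulk, first_layer=min(first, bulk),
            ratio=ratio,
        )
        solver = ProjectionSolver.steady(mesh, BloodProperties(hct=0.0), 0.01)
        field = solver.step(1e-3)
        assert np.isfinite(field.u).all() and np.isfinite(field.p).all()
        assert solver.last_max_rel_div <= 1e-8


class TestExportStl:
    def test_watertight_and_roundtrip(self, tmp_path):
        import trimesh

        geom = build_geometry(False)
        path = tmp_path / "vessel.stl"
        written = export_stl(geom, path)
        assert written.is_watertight
        re = trimesh.load(str(path))
        assert re.is_watertight
        lo, hi = re.bounds
        assert np.allclose(lo, [0, 0, 0], atol=1e-9)
        assert np.allclose(hi, [geom.length, geom.width, 0.01], atol=1e-9)

    def test_flap_raises_triangle_count(self, tmp_path):
        n_plain = len(export_stl(build_geometry(False), tmp_path / "a.stl").faces)
        n_flap = len(export_stl(build_geometry(True), tmp_path / "b.stl").faces)
        assert n_flap > n_plain


class TestMeshIndependence:
    GEOM = {
        "length": 0.05,
        "width": 0.015,
        "branch_outlets": (("Visceral", 0.02, 0.005),),
        "flap_x": (0.015, 0.04),
        "tears": ((0.02, 0.004),),
    }

    def _case(self):
        from aortoflow.pipeline import CaseSpec

        return CaseSpec(
            dissected=False, hct=0.40, intensity="real", geometry_params=self.GEOM,
            outlet_pressures=None,
        )

    def test_identical_sizes_give_zero_change(self):
        rep = mesh_independence(self._case(), [3e-3, 3e-3])
        assert rep[0]["converged"] and rep[1]["converged"]
        assert rep[1]["delta_wss"] == pytest.approx(0.0, abs=1e-12)
        assert rep[1]["delta_flow"] == pytest.approx(0.0, abs=1e-12)

    def test_failure_is_recorded_not_raised(self):
        # a bulk size wider than the band cannot host the boundary layers
        rep = mesh_independence(self._case(), [2e-2, 3e-3])
        assert not rep[0]["converged"] and rep[0]["error"]
        assert rep[1]["converged"]

    def test_increasing_sizes_rejected(self):
        with pytest.raises(ValueError):
            mesh_independence(self._case(), [1e-3, 2e-3])
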