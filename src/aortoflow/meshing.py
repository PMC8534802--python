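"""Structured quadrilateral meshing with boundary-layer grading.

The flow domain is discretized on a tensor-product (rectilinear) grid.
Wall-normal spacing follows a geometric boundary-layer progression — first
layer ``first_layer`` thick, growing by ``expansion_ratio`` per row for
``n_boundary_layers`` rows (or until the bulk size is reached) — on every
wall, including both faces of the dissection flap.  Axial spacing is
uniform at the bulk size with grid lines snapped exactly to outlet edges,
flap ends and tear edges.  The flap itself is represented by rows of
blocked (solid) cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VesselGeometry

__all__ = ["Mesh", "MeshingError", "mesh_geometry", "export_stl", "mesh_independence"]


class MeshingError(RuntimeError):
    pass


def _graded_layers(first: float, ratio: float, bulk: float, n_layers: int):
    """Geometric layer thicknesses from a wall, stopping at bulk size."""
    layers = []
    t = first
    for _ in range(n_layers):
        if t >= bulk:
            break
        layers.append(t)
        t *= ratio
    return layers


def _graded_band(width: float, first: float, ratio: float, bulk: float, n_layers: int):
    """Cell heights across a wall-bounded band: graded, uniform core, graded."""
    layers = _graded_layers(first, ratio, bulk, n_layers)
    core = width - 2.0 * sum(layers)
    if core <= 0:
        raise MeshingError(
            f"geometry too narrow for two boundary layers: band width {width:.4g} m "
            f"vs 2 x {sum(layers):.4g} m of layers"
        )
    n_core = max(1, int(round(core / bulk)))
    heights = layers + [core / n_core] * n_core + layers[::-1]
    return np.asarray(heights)


def _snapped_axis(length: float, bulk: float, breakpoints, min_cells: int = 1):
    """Face coordinates along x: uniform ~bulk spacing, snapped to breakpoints."""
    pts = sorted({0.0, length, *(float(b) for b in breakpoints if 0.0 < b < length)})
    faces = [0.0]
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(min_cells, int(round((b - a) / bulk)))
        faces.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(faces)


@dataclass
class Mesh:
    """Rectilinear staggered-compatible mesh of a :class:`VesselGeometry`.

    ``fluid`` marks open cells (the flap is blocked).  Boundary tags are
    stored per boundary face run (``left_tags[j]``, ``right_tags[j]`` over
    cell rows; ``bottom_tags[i]``, ``top_tags[i]`` over cell columns) and
    are one of ``"inlet"``, ``"wall"`` or ``"outlet:<name>"``.
    """

    xf: np.ndarray
    yf: np.ndarray
    fluid: np.ndarray
    left_tags: list
    right_tags: list
    bottom_tags: list
    top_tags: list
    bulk_size: float
    first_layer_thickness: float
    expansion_ratio: float
    n_boundary_layers: int
    geometry: VesselGeometry

    # -- derived quantities ------------------------------------------------
    @property
    def nx(self) -> int:
        return self.xf.size - 1

    @property
    def ny(self) -> int:
        return self.yf.size - 1

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.xf)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.yf)

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xf[:-1] + self.xf[1:])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.yf[:-1] + self.yf[1:])

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.fluid))

    def cell_areas(self) -> np.ndarray:
        return np.outer(self.dx, self.dy)

    @property
    def nodes(self) -> np.ndarray:
        """(n_nodes, 2) vertex coordinates, x-fastest ordering."""
        X, Y = np.meshgrid(self.xf, self.yf, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    @property
    def cells(self) -> np.ndarray:
        """(n_fluid_cells, 4) CCW quad connectivity into :attr:`nodes`."""
        nyp = self.ny + 1
        quads = []
        for i in range(self.nx):
            for j in range(self.ny):
                if self.fluid[i, j]:
                    n0 = i * nyp + j
                    quads.append((n0, n0 + nyp, n0 + nyp + 1, n0 + 1))
        return np.asarray(quads, dtype=int)

    def boundary_tags(self) -> dict:
        """Map of boundary faces ``(axis, i, j) -> tag``.

        ``axis`` is "x" for faces normal to x (u faces) and "y" for faces
        normal to y; includes the flap (internal solid) faces as
        ``wall:flap``.
        """
        tags = {}
        for j in range(self.ny):
            if self.fluid[0, j]:
                tags[("x", 0, j)] = self.left_tags[j]
            if self.fluid[-1, j]:
                tags[("x", self.nx, j)] = self.right_tags[j]
        for i in range(self.nx):
            if self.fluid[i, 0]:
                tags[("y", i, 0)] = self.bottom_tags[i]
            if self.fluid[i, -1]:
                tags[("y", i, self.ny)] = self.top_tags[i]
        solid = ~self.fluid
        for i in range(self.nx):
            for j in range(self.ny):
                if not solid[i, j]:
                    continue
                if j > 0 and self.fluid[i, j - 1]:
                    tags[("y", i, j)] = "wall:flap"
                if j + 1 < self.ny and self.fluid[i, j + 1]:
                    tags[("y", i, j + 1)] = "wall:flap"
                if i > 0 and self.fluid[i - 1, j]:
                    tags[("x", i, j)] = "wall:flap"
                if i + 1 < self.nx and self.fluid[i + 1, j]:
                    tags[("x", i + 1, j)] = "wall:flap"
        return tags

    def boundary_layer_heights(self) -> np.ndarray:
        """Wall-adjacent row heights from the bottom wall (for auditing)."""
        n = len(
            _graded_layers(
                self.first_layer_thickness,
                self.expansion_ratio,
                self.bulk_size,
                self.n_boundary_layers,
            )
        )
        return self.dy[:n]


def mesh_geometry(
    geom: VesselGeometry,
    bulk_size: float = 2.0e-3,
    first_layer: float = 1.0e-4,
    ratio: float = 1.15,
    n_boundary_layers: int = 5,
) -> Mesh:
    """Mesh a vessel geometry with graded boundary layers.

    ``bulk_size``/``first_layer`` in metres; ``ratio`` >= 1 is the geometric
    expansion of wall-adjacent rows; the flap receives graded layers on
    both of its faces and is blocked with ~0.4 mm solid rows.
    """
    if first_layer > bulk_size:
        raise MeshingError("first_layer must not exceed bulk_size")
    if ratio < 1.0:
        raise MeshingError("expansion ratio must be >= 1")

    # --- axial faces, snapped to every geometric feature -----------------
    breakpoints = []
    for o in geom.outlets:
        if o.side != "distal":
            breakpoints.extend(o.x_interval)
    if geom.dissected:
        breakpoints.extend((geom.flap.x_start, geom.flap.x_end))
        if geom.flap.proximal_cap:
            breakpoints.append(geom.flap.x_start + geom.flap.thickness)
        for tear in geom.flap.tears:
            breakpoints.extend(tear.x_interval)
    xf = _snapped_axis(geom.length, bulk_size, breakpoints)

    # --- wall-normal faces: graded bands, flap slab ----------------------
    if not geom.dissected:
        heights = _graded_band(geom.width, first_layer, ratio, bulk_size, n_boundary_layers)
        yf = np.concatenate([[0.0], np.cumsum(heights)])
        flap_rows = None
    else:
        y_lo, y_hi = geom.flap_y_interval()
        lower = _graded_band(y_lo, first_layer, ratio, bulk_size, n_boundary_layers)
        upper = _graded_band(
            geom.width - y_hi, first_layer, ratio, bulk_size, n_boundary_layers
        )
        n_flap = max(2, int(round(geom.flap.thickness / 4.0e-4)))
        slab = np.full(n_flap, geom.flap.thickness / n_flap)
        heights = np.concatenate([lower, slab, upper])
        yf = np.concatenate([[0.0], np.cumsum(heights)])
        flap_rows = (lower.size, lower.size + n_flap)
    yf[-1] = geom.width  # kill accumulated round-off

    nx, ny = xf.size - 1, yf.size - 1
    xc = 0.5 * (xf[:-1] + xf[1:])

    fluid = np.ones((nx, ny), dtype=bool)
    if geom.dissected:
        j0, j1 = flap_rows
        for x0, x1 in geom.flap.segments():
            cols = (xc > x0 + 1e-12) & (xc < x1 - 1e-12)
            fluid[np.ix_(cols, np.arange(j0, j1))] = False
        if geom.flap.proximal_cap:
            # seal the false lumen's proximal mouth (flap wall attachment)
            x0 = geom.flap.x_start
            x1 = x0 + geom.flap.thickness
            cols = (xc > x0 + 1e-12) & (xc < x1 - 1e-12)
            fluid[np.ix_(cols, np.arange(j1, ny))] = False

    # --- boundary tags ----------------------------------------------------
    left_tags = ["inlet"] * ny
    distal = [o for o in geom.outlets if o.side == "distal"]
    right_tags = [f"outlet:{distal[0].name}" if distal else "wall"] * ny
    bottom_tags = ["wall"] * nx
    top_tags = ["wall"] * nx
    for o in geom.outlets:
        if o.side == "distal":
            continue
        lo, hi = o.x_interval
        cols = np.nonzero((xc > lo + 1e-12) & (xc < hi - 1e-12))[0]
        if cols.size < 2:
            raise MeshingError(
                f"outlet {o.name} resolved by fewer than two faces; refine bulk_size"
            )
        tags = bottom_tags if o.side == "bottom" else top_tags
        for i in cols:
            tags[i] = f"outlet:{o.name}"

    return Mesh(
        xf=xf,
        yf=yf,
        fluid=fluid,
        left_tags=left_tags,
        right_tags=right_tags,
        bottom_tags=bottom_tags,
        top_tags=top_tags,
        bulk_size=bulk_size,
        first_layer_thickness=first_layer,
        expansion_ratio=ratio,
        n_boundary_layers=n_boundary_layers,
        geometry=geom,
    )


def _fluid_rectangles(geom: VesselGeometry):
    """Coarse rectilinear decomposition of the planar fluid region."""
    xs = {0.0, geom.length}
    ys = {0.0, geom.width}
    solid_rects = []
    if geom.dissected:
        y_lo, y_hi = geom.flap_y_interval()
        ys.update((y_lo, y_hi))
        for x0, x1 in geom.flap.segments():
            xs.update((x0, x1))
            solid_rects.append((x0, x1, y_lo, y_hi))
        if geom.flap.proximal_cap:
            x0 = geom.flap.x_start
            x1 = x0 + geom.flap.thickness
            xs.update((x0, x1))
            solid_rects.append((x0, x1, y_hi, geom.width))
    xs = np.array(sorted(xs))
    ys = np.array(sorted(ys))
    xm = 0.5 * (xs[:-1] + xs[1:])
    ym = 0.5 * (ys[:-1] + ys[1:])
    fluid = np.ones((xm.size, ym.size), dtype=bool)
    for x0, x1, y0, y1 in solid_rects:
        fluid &= ~(
            ((xm > x0) & (xm < x1))[:, None] & ((ym > y0) & (ym < y1))[None, :]
        )
    return xs, ys, fluid


def export_stl(geom: VesselGeometry, path, depth: float = 0.01):
    """Write the vessel outline as a watertight binary STL surface.

    The planar outline (channel minus flap pieces) is extruded by
    ``depth`` metres; caps and side walls are triangulated directly from
    a rectilinear decomposition, so the surface is watertight by
    construction.  Returns the :class:`trimesh.Trimesh` that was written,
    so callers can audit watertightness and vertices.
    """
    import trimesh

    xs, ys, fluid = _fluid_rectangles(geom)
    nxr, nyr = fluid.shape
    NY = ys.size

    def node(ix, iy, iz):
        return (ix * NY + iy) * 2 + iz

    verts = np.array(
        [[x, y, z] for x in xs for y in ys for z in (0.0, depth)]
    )
    faces = []
    for i in range(nxr):
        for j in range(nyr):
            if not fluid[i, j]:
                continue
            v = {
                (a, b, c): node(i + a, j + b, c)
                for a in (0, 1)
                for b in (0, 1)
                for c in (0, 1)
            }
            # caps: top CCW seen from +z, bottom reversed
            faces.append((v[0, 0, 1], v[1, 0, 1], v[1, 1, 1]))
            faces.append((v[0, 0, 1], v[1, 1, 1], v[0, 1, 1]))
            faces.append((v[0, 0, 0], v[1, 1, 0], v[1, 0, 0]))
            faces.append((v[0, 0, 0], v[0, 1, 0], v[1, 1, 0]))
            # side walls where the neighbour is solid or outside
            if i == 0 or not fluid[i - 1, j]:  # west, outward -x
                faces.append((v[0, 0, 0], v[0, 1, 1], v[0, 1, 0]))
                faces.append((v[0, 0, 0], v[0, 0, 1], v[0, 1, 1]))
            if i == nxr - 1 or not fluid[i + 1, j]:  # east, outward +x
                faces.append((v[1, 0, 0], v[1, 1, 0], v[1, 1, 1]))
                faces.append((v[1, 0, 0], v[1, 1, 1], v[1, 0, 1]))
            if j == 0 or not fluid[i, j - 1]:  # south, outward -y
                faces.append((v[0, 0, 0], v[1, 0, 0], v[1, 0, 1]))
                faces.append((v[0, 0, 0], v[1, 0, 1], v[0, 0, 1]))
            if j == nyr - 1 or not fluid[i, j + 1]:  # north, outward +y
                faces.append((v[0, 1, 0], v[1, 1, 1], v[1, 1, 0]))
                faces.append((v[0, 1, 0], v[0, 1, 1], v[1, 1, 1]))
    mesh3d = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=True)
    if not mesh3d.is_watertight:  # pragma: no cover - construction guarantee
        raise RuntimeError("extruded surface is not watertight")
    mesh3d.export(str(path))
    return mesh3d


def mesh_independence(case, bulk_sizes, steady_velocity: float | None = None):
    """Grid-refinement study on the steady Newtonian version of a case.

    Runs the case's geometry with a constant inlet (the waveform mean by
    default) and a constant-viscosity analogue of its blood properties at
    each bulk size, and reports peak wall shear stress, total outlet flow
    and the relative change between successive refinements.  Solver
    failures are recorded per size, not raised.

    Parameters
    ----------
    case : CaseSpec
        Factorial case description (geometry + blood + waveform settings).
    bulk_sizes : sequence of float
        Strictly decreasing cell sizes, metres.
    """
    from dataclasses import replace as _replace

    from . import post
    from .pipeline import case_blood, case_geometry, case_waveform
    from .solver import ProjectionSolver, SolverError

    bulk_sizes = [float(b) for b in bulk_sizes]
    if len(bulk_sizes) < 2 or any(
        b2 > b1 for b1, b2 in zip(bulk_sizes[:-1], bulk_sizes[1:])
    ):
        raise ValueError("need >= 2 non-increasing bulk sizes")

    geom = case_geometry(case)
    props = case_blood(case)
    # Newtonian analogue: freeze K at its high-shear plateau
    props = _replace(props, k0=props.k_inf)
    u_mean = steady_velocity if steady_velocity is not None else case_waveform(case).mean()

    rows = []
    prev = None
    for bulk in bulk_sizes:
        row = {"bulk_size": bulk, "converged": False, "peak_wss": np.nan,
               "outlet_flow": np.nan, "delta_wss": np.nan, "delta_flow": np.nan,
               "n_cells": np.nan, "error": ""}
        try:
            mesh = mesh_geometry(
                geom,
                bulk_size=bulk,
                first_layer=min(case.first_layer, bulk),
                ratio=case.expansion_ratio,
                n_boundary_layers=case.n_boundary_layers,
            )
            solver = ProjectionSolver.steady(
                mesh, props, u_mean,
                outlet_pressures=getattr(case, "outlet_pressures", None),
            )
            field = solver.solve_steady()
            wss_all = [
                post.wss_profile(field, mesh, wid).wss.max()
                for wid in post.wall_ids(mesh)
            ]
            flows = post.outlet_mass_flows(field, mesh, props)
            row.update(
                converged=True,
                peak_wss=float(max(wss_all)),
                outlet_flow=float(sum(f.volumetric_m2_s for f in flows.values())),
                n_cells=mesh.n_cells,
            )
            if prev is not None:
                row["delta_wss"] = abs(row["peak_wss"] - prev["peak_wss"]) / abs(prev["peak_wss"])
                row["delta_flow"] = abs(row["outlet_flow"] - prev["outlet_flow"]) / abs(prev["outlet_flow"])
            prev = row
        except (MeshingError, SolverError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return rows
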