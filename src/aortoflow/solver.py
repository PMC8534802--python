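"""Pulsatile incompressible laminar flow on the 2-D staggered grid.

Fractional-step (projection) scheme, first order in time:

1. viscosity update  — apparent viscosity per cell from the previous
   step's shear-rate field (Picard lagging of the Quemada closure);
2. momentum predictor — explicit first-order upwind advection, implicit
   (backward-Euler) variable-viscosity diffusion;
3. pressure-increment Poisson solve (incremental projection: the
   predictor carries the old pressure gradient, so no O(dt) wall-slip
   error) with Dirichlet pressure on outlet faces and homogeneous
   Neumann elsewhere; the matrix is factorized once per mesh;
4. velocity correction and pressure accumulation — the corrected field
   is discretely divergence free to solver precision.

Boundary conditions: velocity inlet (plug or parabolic profile of a
periodic waveform), fixed-pressure outlets with zero tangential stress,
no-slip rigid walls (including both flap faces).  The time step is fixed
at ``period / steps_per_cycle`` so that phases align exactly across
cycles; the advective CFL condition is checked every step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import operators
from .rheology import BloodProperties, viscosity_field

__all__ = [
    "SolverError",
    "StepSizeError",
    "FlowField",
    "BoundaryConditions",
    "CycleSeries",
    "ProjectionSolver",
    "step",
    "run_cycles",
    "check_laminar",
]

CFL_LIMIT = 0.9
DT_CEILING = 1.0e-3  # s


class SolverError(RuntimeError):
    pass


class StepSizeError(SolverError):
    pass


@dataclass
class FlowField:
    """Velocity/pressure snapshot on the staggered grid at time ``t``."""

    u: np.ndarray  # (nx+1, ny) m/s
    v: np.ndarray  # (nx, ny+1) m/s
    p: np.ndarray  # (nx, ny) Pa
    t: float  # s
    mu: np.ndarray  # (nx, ny) Pa*s, viscosity used for this step

    def copy(self) -> "FlowField":
        return FlowField(self.u.copy(), self.v.copy(), self.p.copy(), self.t, self.mu.copy())


@dataclass
class BoundaryConditions:
    """Inlet waveform/constant + per-outlet static gauge pressures (Pa)."""

    inlet: object  # InletWaveform (callable) or float, m/s
    inlet_profile: str = "plug"
    outlet_pressures: Optional[dict] = None

    def inlet_velocity(self, t: float) -> float:
        if callable(self.inlet):
            return float(self.inlet(t))
        return float(self.inlet)

    def outlet_pressure(self, name: str) -> float:
        if not self.outlet_pressures:
            return 0.0
        return float(self.outlet_pressures.get(name, 0.0))


# --------------------------------------------------------------------------
# generic staggered momentum component
# --------------------------------------------------------------------------

_FIXED, _INTERIOR, _OUTLET = 0, 1, 2


class _ComponentSystem:
    """Implicit-diffusion system for one velocity component.

    Written in a canonical frame where the component's normal axis is
    "x": faces are (n1+1, n2) over cells (n1, n2).  The v component uses
    the same code with all arrays transposed.  Link structure (neighbour
    indices, geometric conductance factors, viscosity gather indices) is
    precomputed once; only the per-step viscosities change.
    """

    def __init__(self, fluid, xf, yf, nminus_kind, nplus_kind, tminus_kind, tplus_kind):
        n1, n2 = fluid.shape
        self.n1, self.n2 = n1, n2
        xc = 0.5 * (xf[:-1] + xf[1:])
        yc = 0.5 * (yf[:-1] + yf[1:])
        dx = np.diff(xf)
        dy = np.diff(yf)
        self.face_shape = (n1 + 1, n2)

        code = np.zeros(self.face_shape, dtype=np.int8)
        for j in range(n2):
            if fluid[0, j] and nminus_kind[j] == "inlet":
                code[0, j] = _FIXED  # dynamic Dirichlet
            if fluid[n1 - 1, j] and nplus_kind[j] == "outlet":
                code[n1, j] = _OUTLET
            if fluid[0, j] and nminus_kind[j] == "outlet":
                code[0, j] = _OUTLET
        for i in range(1, n1):
            for j in range(n2):
                if fluid[i - 1, j] and fluid[i, j]:
                    code[i, j] = _INTERIOR
        self.code = code
        self.is_dynamic_inlet = np.zeros(self.face_shape, dtype=bool)
        for j in range(n2):
            self.is_dynamic_inlet[0, j] = fluid[0, j] and nminus_kind[j] == "inlet"

        uid = -np.ones(self.face_shape, dtype=int)
        unknowns = np.argwhere(code > 0)
        for k, (i, j) in enumerate(unknowns):
            uid[i, j] = k
        self.uid = uid
        self.n_unknown = len(unknowns)

        interior = [(i, j) for i, j in unknowns if code[i, j] == _INTERIOR]
        outlets = [(i, j) for i, j in unknowns if code[i, j] == _OUTLET]
        self.int_rows = np.array([uid[i, j] for i, j in interior], dtype=int)
        self.int_flat = np.array(
            [i * n2 + j for i, j in interior], dtype=int
        )  # into face arrays
        K = len(interior)

        vol = np.empty(K)
        geo = {d: np.zeros(K) for d in "EWNS"}
        mu_idx = {d: np.zeros(K, dtype=int) for d in "EWNS"}
        mu_src = {"E": "cell", "W": "cell", "N": "corner", "S": "corner"}
        nb_col = {d: -np.ones(K, dtype=int) for d in "EWNS"}
        nb_flat = {d: -np.ones(K, dtype=int) for d in "EWNS"}
        adv_dist = {d: np.ones(K) for d in "EWNS"}
        adv_mode = {d: np.zeros(K, dtype=np.int8) for d in "NS"}  # 0 array,1 wall,2 copy

        def t_kind(kinds, i):
            if 0 < i < n1:
                a, b = kinds[i - 1], kinds[i]
                return "wall" if "wall" in (a, b) else "open"
            return kinds[min(max(i, 0), n1 - 1)]

        for k, (i, j) in enumerate(interior):
            vol[k] = (xc[i] - xc[i - 1]) * dy[j]
            # E/W: through cell centres (i, j) / (i-1, j)
            geo["E"][k] = dy[j] / dx[i]
            mu_idx["E"][k] = i * n2 + j
            adv_dist["E"][k] = dx[i]
            nb_flat["E"][k] = (i + 1) * n2 + j
            if code[i + 1, j] > 0:
                nb_col["E"][k] = uid[i + 1, j]
            geo["W"][k] = dy[j] / dx[i - 1]
            mu_idx["W"][k] = (i - 1) * n2 + j
            adv_dist["W"][k] = dx[i - 1]
            nb_flat["W"][k] = (i - 1) * n2 + j
            if code[i - 1, j] > 0:
                nb_col["W"][k] = uid[i - 1, j]
            # N/S: through corners (i, j+1) / (i, j)
            w_cv = xc[i] - xc[i - 1]
            # --- north
            if j + 1 < n2 and fluid[i - 1, j + 1] and fluid[i, j + 1]:
                dist = yc[j + 1] - yc[j]
                geo["N"][k] = w_cv / dist
                nb_col["N"][k] = uid[i, j + 1]
                nb_flat["N"][k] = i * n2 + (j + 1)
                adv_dist["N"][k] = dist
                adv_mode["N"][k] = 0
            else:
                wall = True
                if j + 1 == n2 and t_kind(tplus_kind, i) == "open":
                    wall = False
                if wall:
                    dist = yf[j + 1] - yc[j]
                    geo["N"][k] = w_cv / dist
                    adv_dist["N"][k] = dist
                    adv_mode["N"][k] = 1
                else:
                    geo["N"][k] = 0.0
                    adv_mode["N"][k] = 2
            mu_idx["N"][k] = i * (n2 + 1) + (j + 1)
            # --- south
            if j - 1 >= 0 and fluid[i - 1, j - 1] and fluid[i, j - 1]:
                dist = yc[j] - yc[j - 1]
                geo["S"][k] = w_cv / dist
                nb_col["S"][k] = uid[i, j - 1]
                nb_flat["S"][k] = i * n2 + (j - 1)
                adv_dist["S"][k] = dist
                adv_mode["S"][k] = 0
            else:
                wall = True
                if j == 0 and t_kind(tminus_kind, i) == "open":
                    wall = False
                if wall:
                    dist = yc[j] - yf[j]
                    geo["S"][k] = w_cv / dist
                    adv_dist["S"][k] = dist
                    adv_mode["S"][k] = 1
                else:
                    geo["S"][k] = 0.0
                    adv_mode["S"][k] = 2
            mu_idx["S"][k] = i * (n2 + 1) + j

        self.vol = vol
        self.geo = geo
        self.mu_idx = mu_idx
        self.mu_src = mu_src
        self.nb_col = nb_col
        self.nb_flat = nb_flat
        self.adv_dist = adv_dist
        self.adv_mode = adv_mode
        self.own_i = np.array([i for i, _ in interior], dtype=int)
        self.own_j = np.array([j for _, j in interior], dtype=int)

        # outlet (zero-gradient) rows
        o_rows, o_nb_col, o_nb_flat = [], [], []
        for i, j in outlets:
            i_nb = i - 1 if i == n1 else i + 1
            o_rows.append(uid[i, j])
            if code[i_nb, j] > 0:
                o_nb_col.append(uid[i_nb, j])
                o_nb_flat.append(-1)
            else:
                o_nb_col.append(-1)
                o_nb_flat.append(i_nb * n2 + j)
        self.o_rows = np.array(o_rows, dtype=int)
        self.o_nb_col = np.array(o_nb_col, dtype=int)
        self.o_nb_flat = np.array(o_nb_flat, dtype=int)
        self.unknown_flat = np.array([i * n2 + j for i, j in unknowns], dtype=int)

        # fixed sparsity pattern
        rows = [self.int_rows]
        cols = [self.int_rows]
        self._data_slices = {}
        pos = K
        for d in "EWNS":
            m = nb_col[d] >= 0
            rows.append(self.int_rows[m])
            cols.append(nb_col[d][m])
            self._data_slices[d] = (pos, pos + int(m.sum()), m)
            pos += int(m.sum())
        rows.append(self.o_rows)
        cols.append(self.o_rows)
        self._o_diag = (pos, pos + len(self.o_rows))
        pos += len(self.o_rows)
        m = self.o_nb_col >= 0
        rows.append(self.o_rows[m])
        cols.append(self.o_nb_col[m])
        self._o_off = (pos, pos + int(m.sum()), m)
        pos += int(m.sum())
        self._rows = np.concatenate(rows) if rows else np.array([], int)
        self._cols = np.concatenate(cols) if cols else np.array([], int)
        self._nnz = pos
        self._K = K
        # banded storage: the lexicographic unknown ordering keeps the
        # 5-point stencil inside a narrow band solved by LAPACK gbsv
        if self.n_unknown:
            self._bw = int(np.abs(self._rows - self._cols).max(initial=0))
            self._ab_pos = (self._bw + self._rows - self._cols) * self.n_unknown + self._cols
        else:
            self._bw = 0
            self._ab_pos = np.array([], int)

    def advection(self, own: np.ndarray, other: np.ndarray) -> np.ndarray:
        """First-order upwind u·grad(own) at interior unknown faces."""
        K = self._K
        if K == 0:
            return np.zeros(0)
        fo = own.ravel()
        val = fo[self.int_flat]
        uE = fo[self.nb_flat["E"]]
        uW = fo[self.nb_flat["W"]]
        ddx = np.where(
            val > 0,
            (val - uW) / self.adv_dist["W"],
            (uE - val) / self.adv_dist["E"],
        )
        i, j = self.own_i, self.own_j
        vbar = 0.25 * (
            other[i - 1, j] + other[i - 1, j + 1] + other[i, j] + other[i, j + 1]
        )
        uN = np.where(
            self.adv_mode["N"] == 0,
            fo[np.maximum(self.nb_flat["N"], 0)],
            np.where(self.adv_mode["N"] == 1, 0.0, val),
        )
        uS = np.where(
            self.adv_mode["S"] == 0,
            fo[np.maximum(self.nb_flat["S"], 0)],
            np.where(self.adv_mode["S"] == 1, 0.0, val),
        )
        ddy = np.where(
            vbar > 0,
            (val - uS) / self.adv_dist["S"],
            (uN - val) / self.adv_dist["N"],
        )
        return val * ddx + vbar * ddy

    def solve(self, mu_cell, mu_corner, rho, dt, faces_known, forcing, lu_cache=None):
        """Assemble and solve the implicit predictor; returns face array.

        ``forcing`` is the explicit acceleration (advection + old pressure
        gradient over rho) sampled at the interior unknown faces.
        """
        out = faces_known.copy()
        if self.n_unknown == 0:
            return out, lu_cache
        K = self._K
        fo = faces_known.ravel()
        data = np.zeros(self._nnz)
        rhs = np.zeros(self.n_unknown)

        inertia = rho * self.vol / dt
        diag = inertia.copy()
        mu_flat = {"cell": mu_cell.ravel(), "corner": mu_corner.ravel()}
        rhs_int = inertia * (fo[self.int_flat] - dt * forcing)
        for d in "EWNS":
            g = mu_flat[self.mu_src[d]][self.mu_idx[d]] * self.geo[d]
            diag += g
            lo, hi, m = self._data_slices[d]
            data[lo:hi] = -g[m]
            known = (~m) & (self.nb_flat[d] >= 0) & (g > 0)
            if np.any(known):
                rhs_int[known] += g[known] * fo[self.nb_flat[d][known]]
        data[:K] = diag
        rhs[self.int_rows] = rhs_int

        lo, hi = self._o_diag
        data[lo:hi] = 1.0
        lo, hi, m = self._o_off
        data[lo:hi] = -1.0
        if np.any(~m):
            rhs[self.o_rows[~m]] = fo[self.o_nb_flat[~m]]

        ab = np.zeros((2 * self._bw + 1, self.n_unknown))
        ab.ravel()[self._ab_pos] = data
        sol = la.solve_banded((self._bw, self._bw), ab, rhs)
        out.ravel()[self.unknown_flat] = sol
        return out, None


# --------------------------------------------------------------------------


class ProjectionSolver:
    """Time-marching projection solver bound to one mesh + blood + BCs."""

    def __init__(self, mesh, props: BloodProperties, bc: BoundaryConditions):
        self.mesh = mesh
        self.props = props
        self.bc = bc
        nx, ny = mesh.nx, mesh.ny
        self.nx, self.ny = nx, ny
        fluid = mesh.fluid

        is_out_r = [t.startswith("outlet") for t in mesh.right_tags]
        is_out_b = [t.startswith("outlet") for t in mesh.bottom_tags]
        is_out_t = [t.startswith("outlet") for t in mesh.top_tags]

        # u component: canonical frame
        self._usys = _ComponentSystem(
            fluid,
            mesh.xf,
            mesh.yf,
            nminus_kind=["inlet" if t == "inlet" else "wall" for t in mesh.left_tags],
            nplus_kind=["outlet" if o else "wall" for o in is_out_r],
            tminus_kind=["open" if o else "wall" for o in is_out_b],
            tplus_kind=["open" if o else "wall" for o in is_out_t],
        )
        # v component: swapped frame (normal = y)
        self._vsys = _ComponentSystem(
            fluid.T,
            mesh.yf,
            mesh.xf,
            nminus_kind=["outlet" if o else "wall" for o in is_out_b],
            nplus_kind=["outlet" if o else "wall" for o in is_out_t],
            tminus_kind=["wall"] * ny,  # inlet plane: zero tangential velocity
            tplus_kind=["open" if t.startswith("outlet") else "wall" for t in mesh.right_tags],
        )

        self._build_poisson()
        self._inlet_profile = self._make_inlet_profile()
        self._inlet_rows = np.array(
            [j for j in range(ny) if fluid[0, j] and mesh.left_tags[j] == "inlet"],
            dtype=int,
        )

        # initial state: quiescent
        self.u = np.zeros((nx + 1, ny))
        self.v = np.zeros((nx, ny + 1))
        self.p = np.zeros((nx, ny))
        self.mu = viscosity_field(np.zeros((nx, ny)), props)
        self.t = 0.0
        self.last_max_rel_div = 0.0
        self.last_mass_imbalance = 0.0
        self._apply_inlet(self.u, 0.0)

    # -- construction helpers ---------------------------------------------
    def _make_inlet_profile(self) -> np.ndarray:
        """Per-row shape factors with unit mean over the inlet span."""
        mesh = self.mesh
        rows = [
            j
            for j in range(mesh.ny)
            if mesh.fluid[0, j] and mesh.left_tags[j] == "inlet"
        ]
        yc = mesh.yc[rows]
        dy = mesh.dy[rows]
        span = dy.sum()
        if self.bc.inlet_profile == "plug":
            shape = np.ones(len(rows))
        elif self.bc.inlet_profile == "parabolic":
            y0 = mesh.yf[rows[0]]
            eta = (yc - y0) / span
            shape = 6.0 * eta * (1.0 - eta)
        else:
            raise ValueError(f"unknown inlet profile {self.bc.inlet_profile!r}")
        shape /= (shape * dy).sum() / span  # unit mean -> exact flux control
        profile = np.zeros(mesh.ny)
        profile[rows] = shape
        return profile

    def _apply_inlet(self, u: np.ndarray, t: float) -> None:
        u[0, :] = self.bc.inlet_velocity(t) * self._inlet_profile

    def _build_poisson(self) -> None:
        mesh = self.mesh
        nx, ny = self.nx, self.ny
        fluid = mesh.fluid
        xc, yc, xf, yf, dx, dy = mesh.xc, mesh.yc, mesh.xf, mesh.yf, mesh.dx, mesh.dy

        pid = -np.ones((nx, ny), dtype=int)
        cells = np.argwhere(fluid)
        for k, (i, j) in enumerate(cells):
            pid[i, j] = k
        self._pid = pid
        n = len(cells)

        rows, cols, data = [], [], []
        diag = np.zeros(n)
        # Dirichlet (outlet) faces: phi_face = dt*(p_out - p_cell)/rho,
        # recomputed every step for the incremental pressure update.
        dir_entries = []  # (row, T, cell_i, cell_j, outlet_tag)
        for k, (i, j) in enumerate(cells):
            # east
            if i + 1 < nx and fluid[i + 1, j]:
                T = dy[j] / (xc[i + 1] - xc[i])
                diag[k] += T
                rows.append(k)
                cols.append(pid[i + 1, j])
                data.append(-T)
            elif i + 1 == nx and mesh.right_tags[j].startswith("outlet"):
                T = dy[j] / (xf[nx] - xc[i])
                diag[k] += T
                dir_entries.append((k, T, i, j, mesh.right_tags[j], "R"))
            # west
            if i - 1 >= 0 and fluid[i - 1, j]:
                T = dy[j] / (xc[i] - xc[i - 1])
                diag[k] += T
                rows.append(k)
                cols.append(pid[i - 1, j])
                data.append(-T)
            # north
            if j + 1 < ny and fluid[i, j + 1]:
                T = dx[i] / (yc[j + 1] - yc[j])
                diag[k] += T
                rows.append(k)
                cols.append(pid[i, j + 1])
                data.append(-T)
            elif j + 1 == ny and mesh.top_tags[i].startswith("outlet"):
                T = dx[i] / (yf[ny] - yc[j])
                diag[k] += T
                dir_entries.append((k, T, i, j, mesh.top_tags[i], "T"))
            # south
            if j - 1 >= 0 and fluid[i, j - 1]:
                T = dx[i] / (yc[j] - yc[j - 1])
                diag[k] += T
                rows.append(k)
                cols.append(pid[i, j - 1])
                data.append(-T)
            elif j == 0 and mesh.bottom_tags[i].startswith("outlet"):
                T = dx[i] / (yc[0] - yf[0])
                diag[k] += T
                dir_entries.append((k, T, i, j, mesh.bottom_tags[i], "B"))
        rows.extend(range(n))
        cols.extend(range(n))
        data.extend(diag)
        L = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsc()
        self._poisson_lu = spla.splu(L)
        self._dir_entries = dir_entries
        self._pcells = cells

    def _phi_out(self, tag: str) -> float:
        """Outlet pressure in phi units BEFORE the dt/rho scaling (i.e. Pa)."""
        return self.bc.outlet_pressure(tag.split(":", 1)[1])

    # -- stepping ----------------------------------------------------------
    def _cfl_number(self, dt: float) -> float:
        """Advective Courant number of the current field for step ``dt``."""
        mesh = self.mesh
        dx, dy = mesh.dx, mesh.dy
        dx_loc = np.minimum(dx[:-1], dx[1:])
        cu = np.abs(self.u[1:-1, :]) * dt / dx_loc[:, None]
        dy_loc = np.minimum(dy[:-1], dy[1:])
        cv = np.abs(self.v[:, 1:-1]) * dt / dy_loc[None, :]
        return float(max(cu.max(initial=0.0), cv.max(initial=0.0)))

    def _check_cfl(self, dt: float) -> None:
        cfl = self._cfl_number(dt)
        if cfl > CFL_LIMIT:
            raise StepSizeError(
                f"advective CFL {cfl:.3f} exceeds {CFL_LIMIT} at t={self.t:.4f}s "
                f"(dt={dt:.3e}s); reduce the step size"
            )

    def step_adaptive(self, dt_macro: float, target: float = 0.6) -> FlowField:
        """Advance exactly ``dt_macro`` using CFL-limited substeps.

        The substep count is chosen so each substep's Courant number stays
        near ``target`` (re-evaluated as the field evolves), which keeps
        macro steps — and therefore cycle phases — exactly aligned while
        honouring the advective stability bound.
        """
        remaining = dt_macro
        while remaining > 1e-15:
            c1 = self._cfl_number(1.0)  # Courant number per second of dt
            dt_ok = target / c1 if c1 > 0 else remaining
            n = max(1, int(np.ceil(remaining / dt_ok - 1e-12)))
            self.step(remaining / n)
            remaining -= remaining / n
        return self.state()

    def _corner_viscosity(self, mu_cell: np.ndarray) -> np.ndarray:
        nx, ny = self.nx, self.ny
        fluid = self.mesh.fluid.astype(float)
        w = np.zeros((nx + 2, ny + 2))
        m = np.zeros((nx + 2, ny + 2))
        w[1:-1, 1:-1] = mu_cell * self.mesh.fluid
        m[1:-1, 1:-1] = fluid
        num = w[:-1, :-1] + w[1:, :-1] + w[:-1, 1:] + w[1:, 1:]
        den = m[:-1, :-1] + m[1:, :-1] + m[:-1, 1:] + m[1:, 1:]
        out = np.where(den > 0, num / np.maximum(den, 1), self.props.mu_p)
        return out

    def step(self, dt: float) -> FlowField:
        """Advance one time step; returns the new state (also kept)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        mesh, props = self.mesh, self.props
        rho = props.rho
        self._check_cfl(dt)

        gamma = operators.shear_rate(self.u, self.v, mesh)
        mu_cell = viscosity_field(gamma, props)
        mu_corner = self._corner_viscosity(mu_cell)

        t_new = self.t + dt
        u_known = self.u.copy()
        self._apply_inlet(u_known, t_new)
        v_known = self.v.copy()

        adv_u = self._usys.advection(self.u, self.v)
        adv_v = self._vsys.advection(self.v.T, self.u.T)

        # explicit old-pressure gradient (incremental projection)
        gpu = np.zeros_like(self.u)
        gpu[1:-1, :] = (self.p[1:, :] - self.p[:-1, :]) / (
            mesh.xc[1:] - mesh.xc[:-1]
        )[:, None]
        gpv = np.zeros_like(self.v)
        gpv[:, 1:-1] = (self.p[:, 1:] - self.p[:, :-1]) / (
            mesh.yc[1:] - mesh.yc[:-1]
        )[None, :]
        forcing_u = adv_u + gpu.ravel()[self._usys.int_flat] / rho
        forcing_v = adv_v + gpv.T.ravel()[self._vsys.int_flat] / rho

        u_star, _ = self._usys.solve(mu_cell, mu_corner, rho, dt, u_known, forcing_u)
        v_star_T, _ = self._vsys.solve(
            mu_cell.T, mu_corner.T, rho, dt, v_known.T, forcing_v
        )
        v_star = v_star_T.T

        # pressure-increment Poisson: L phi = -div(u*), phi = dt dp / rho
        div = operators.divergence(u_star, v_star, mesh)
        rhs = -div[self.mesh.fluid]
        phi_out = self._phi_out_faces(dt, rho)
        for (k, T, _i, _j, _tag, _kind), po in zip(self._dir_entries, phi_out):
            rhs[k] += T * po
        phi_vec = self._poisson_lu.solve(rhs)
        phi = np.zeros((self.nx, self.ny))
        phi[self.mesh.fluid] = phi_vec

        self._correct(u_star, v_star, phi, phi_out, dt, rho)
        self.u, self.v = u_star, v_star
        self.p = self.p + rho * phi / dt
        self.mu = mu_cell
        self.t = t_new
        self._diagnose()
        return self.state()

    def _phi_out_faces(self, dt: float, rho: float) -> list:
        """Dirichlet increment phi at each outlet face.

        The accumulated pressure is driven toward the prescribed outlet
        value: phi_face = dt * (p_out - p_cell) / rho, first-order
        extrapolation of the current pressure to the face.
        """
        out = []
        for _k, _T, i, j, tag, _kind in self._dir_entries:
            p_out = self._phi_out(tag)
            out.append(dt * (p_out - self.p[i, j]) / rho)
        return out

    def _correct(self, u, v, phi, phi_out, dt, rho) -> None:
        mesh = self.mesh
        nx, ny = self.nx, self.ny
        xc, yc, xf, yf = mesh.xc, mesh.yc, mesh.xf, mesh.yf
        fluid = mesh.fluid

        # interior u faces
        both = fluid[:-1, :] & fluid[1:, :]
        dxc = (xc[1:] - xc[:-1])[:, None]
        du = np.zeros_like(u)
        du[1:-1, :][both] = ((phi[1:, :] - phi[:-1, :]) / dxc)[both]
        u -= du
        # interior v faces
        bothv = fluid[:, :-1] & fluid[:, 1:]
        dyc = (yc[1:] - yc[:-1])[None, :]
        dv = np.zeros_like(v)
        dv[:, 1:-1][bothv] = ((phi[:, 1:] - phi[:, :-1]) / dyc)[bothv]
        v -= dv
        # outlet faces (Dirichlet pressure)
        for (_k, _T, i, j, _tag, kind), po in zip(self._dir_entries, phi_out):
            if kind == "R":
                u[nx, j] -= (po - phi[nx - 1, j]) / (xf[nx] - xc[nx - 1])
            elif kind == "B":
                v[i, 0] -= (phi[i, 0] - po) / (yc[0] - yf[0])
            else:  # top
                v[i, ny] -= (po - phi[i, ny - 1]) / (yf[ny] - yc[ny - 1])

    def _diagnose(self) -> None:
        mesh = self.mesh
        div = operators.divergence(self.u, self.v, mesh)
        dx, dy = mesh.dx, mesh.dy
        flux_scale = (
            np.abs(self.u[1:, :] * dy[None, :])
            + np.abs(self.u[:-1, :] * dy[None, :])
            + np.abs(self.v[:, 1:] * dx[:, None])
            + np.abs(self.v[:, :-1] * dx[:, None])
        )
        floor = 1e-30 + 1e-3 * flux_scale[mesh.fluid].max(initial=0.0)
        rel = np.abs(div[mesh.fluid]) / np.maximum(flux_scale[mesh.fluid], floor)
        self.last_max_rel_div = float(rel.max(initial=0.0))

        q_in = self.inlet_flow()
        q_out = sum(self.outlet_flows().values())
        denom = max(abs(q_in), 1e-12)
        self.last_mass_imbalance = abs(q_out - q_in) / denom if abs(q_in) > 1e-12 else 0.0

    # -- measurements ------------------------------------------------------
    def inlet_flow(self) -> float:
        """Volumetric inflow per unit depth, m^2/s."""
        return float((self.u[0, :] * self.mesh.dy).sum())

    def outlet_flows(self) -> dict:
        """Volumetric outflow per unit depth per outlet name, m^2/s."""
        mesh = self.mesh
        flows: dict = {}
        for j in range(self.ny):
            tag = mesh.right_tags[j]
            if tag.startswith("outlet") and mesh.fluid[-1, j]:
                flows[tag[7:]] = flows.get(tag[7:], 0.0) + self.u[-1, j] * mesh.dy[j]
        for i in range(self.nx):
            tag_b = mesh.bottom_tags[i]
            if tag_b.startswith("outlet") and mesh.fluid[i, 0]:
                flows[tag_b[7:]] = flows.get(tag_b[7:], 0.0) + (-self.v[i, 0]) * mesh.dx[i]
            tag_t = mesh.top_tags[i]
            if tag_t.startswith("outlet") and mesh.fluid[i, -1]:
                flows[tag_t[7:]] = flows.get(tag_t[7:], 0.0) + self.v[i, -1] * mesh.dx[i]
        return flows

    def state(self) -> FlowField:
        return FlowField(self.u.copy(), self.v.copy(), self.p.copy(), self.t, self.mu.copy())

    def set_state(self, field: FlowField) -> None:
        self.u = field.u.copy()
        self.v = field.v.copy()
        self.p = field.p.copy()
        self.t = field.t
        self.mu = field.mu.copy()

    # -- drivers -----------------------------------------------------------
    @classmethod
    def steady(cls, mesh, props, inlet_velocity: float, profile: str = "parabolic",
               outlet_pressures: Optional[dict] = None):
        """Solver configured for a constant-inlet (steady) problem."""
        bc = BoundaryConditions(
            inlet=float(inlet_velocity),
            inlet_profile=profile,
            outlet_pressures=outlet_pressures,
        )
        return cls(mesh, props, bc)

    def solve_steady(
        self,
        dt: float | None = None,
        tol: float = 1.0e-7,
        max_steps: int = 8000,
        init_from_profile: bool = True,
    ) -> FlowField:
        """March to steady state; returns the converged field.

        Convergence: max |du| per step below ``tol * max|u|``.  The field
        is initialized from the inlet profile extruded downstream, which
        is exact for developed channel flow.
        """
        u_in = self.bc.inlet_velocity(0.0)
        if dt is None:
            dx_min = float(min(self.mesh.dx.min(), 1.0))
            dt = min(20e-3, 0.5 * CFL_LIMIT * dx_min / max(2.0 * u_in, 1e-9))
        if init_from_profile:
            fluid = self.mesh.fluid
            self.u = np.tile((u_in * self._inlet_profile)[None, :], (self.nx + 1, 1))
            open_face = np.ones_like(self.u, dtype=bool)
            open_face[1:-1, :] = fluid[:-1, :] & fluid[1:, :]
            open_face[-1, :] = fluid[-1, :]
            self.u[~open_face] = 0.0
            self._apply_inlet(self.u, 0.0)
        for n in range(max_steps):
            u_old = self.u.copy()
            v_old = self.v.copy()
            self.step_adaptive(dt)
            delta = max(
                np.abs(self.u - u_old).max(initial=0.0),
                np.abs(self.v - v_old).max(initial=0.0),
            )
            scale = max(np.abs(self.u).max(initial=0.0), 1e-12)
            if delta <= tol * scale:
                return self.state()
        raise SolverError(
            f"steady solve did not converge in {max_steps} steps "
            f"(last relative change {delta / scale:.3e})"
        )

    def run_cycles(
        self,
        n_cycles: int,
        discard: int = 3,
        steps_per_cycle: int | None = None,
        snapshots_per_cycle: int = 25,
    ) -> "CycleSeries":
        """March ``n_cycles`` periods; keep snapshots after ``discard``.

        The time step is ``period / steps_per_cycle`` (default: smallest
        count that respects the 1 ms ceiling), so snapshot phases align
        exactly across cycles; per-cycle convergence is the RMS
        phase-matched velocity difference between successive cycles,
        normalized by the peak velocity.
        """
        if not callable(self.bc.inlet):
            raise SolverError("run_cycles needs a periodic inlet waveform")
        if n_cycles <= discard:
            raise ValueError("n_cycles must exceed the discard window")
        period = float(self.bc.inlet.period)
        if steps_per_cycle is None:
            steps_per_cycle = int(np.ceil(period / DT_CEILING))
        dt = period / steps_per_cycle
        every = max(1, steps_per_cycle // snapshots_per_cycle)

        log = {"t": [], "inlet_flow": [], "outlet_flows": [], "max_rel_div": [],
               "mass_imbalance": []}
        phase_snaps: list = []
        retained: list = []
        peak_u = 0.0
        cycle_metrics = []
        prev_cycle = None
        for c in range(n_cycles):
            this_cycle = []
            for s in range(steps_per_cycle):
                self.step_adaptive(dt)
                log["t"].append(self.t)
                log["inlet_flow"].append(self.inlet_flow())
                log["outlet_flows"].append(self.outlet_flows())
                log["max_rel_div"].append(self.last_max_rel_div)
                log["mass_imbalance"].append(self.last_mass_imbalance)
                peak_u = max(peak_u, float(np.abs(self.u).max()), float(np.abs(self.v).max()))
                if (s + 1) % every == 0:
                    this_cycle.append((self.u.copy(), self.v.copy()))
                    if c >= discard:
                        retained.append(self.state())
            if prev_cycle is not None:
                num = 0.0
                cnt = 0
                for (ua, va), (ub, vb) in zip(prev_cycle, this_cycle):
                    num += float(((ua - ub) ** 2).sum() + ((va - vb) ** 2).sum())
                    cnt += ua.size + va.size
                rms = np.sqrt(num / max(cnt, 1))
                cycle_metrics.append(rms / max(peak_u, 1e-12))
            prev_cycle = this_cycle
            phase_snaps.append(this_cycle)
        return CycleSeries(
            fields=retained,
            cycle_metrics=cycle_metrics,
            dt=dt,
            period=period,
            discard=discard,
            peak_velocity=peak_u,
            log=log,
            mesh=self.mesh,
            props=self.props,
            bc=self.bc,
        )


@dataclass
class CycleSeries:
    """Retained snapshots + per-step log of a multi-cycle run."""

    fields: list
    cycle_metrics: list  # phase-matched RMS diff / peak velocity, per cycle pair
    dt: float
    period: float
    discard: int
    peak_velocity: float
    log: dict
    mesh: object
    props: object
    bc: object

    def at_time(self, t: float) -> FlowField:
        """Retained snapshot closest to absolute time ``t`` (s)."""
        if not self.fields:
            raise ValueError("no retained snapshots")
        times = np.array([f.t for f in self.fields])
        return self.fields[int(np.argmin(np.abs(times - t)))]

    def at_phase(self, phase: float) -> FlowField:
        """Retained snapshot closest to cycle phase ``phase`` in [0, 1)."""
        if not self.fields:
            raise ValueError("no retained snapshots")
        times = np.array([f.t for f in self.fields])
        ph = np.mod(times / self.period, 1.0)
        d = np.abs(np.mod(ph - phase + 0.5, 1.0) - 0.5)
        return self.fields[int(np.argmin(d))]


# --------------------------------------------------------------------------
# module-level operation surface
# --------------------------------------------------------------------------


def step(field: FlowField, dt: float, mesh, bc: BoundaryConditions, props) -> FlowField:
    """Advance a flow field one time step (stateless convenience wrapper)."""
    solver = ProjectionSolver(mesh, props, bc)
    solver.set_state(field)
    return solver.step(dt)


def run_cycles(mesh, props, bc, n_cycles: int, discard: int = 3, **kw) -> CycleSeries:
    """Run the multi-cycle protocol from a quiescent start."""
    solver = ProjectionSolver(mesh, props, bc)
    return solver.run_cycles(n_cycles, discard=discard, **kw)


LAMINAR_RE_LIMIT = 2300.0
RE_REFERENCE_SHEAR = 100.0  # 1/s, characteristic shear for mu_char


def check_laminar(series: CycleSeries, props=None, mesh=None) -> dict:
    """Peak Reynolds number per inlet/outlet; flags Re above 2300.

    Re = rho * U_peak * D / mu_char with D the local channel/branch width
    and mu_char the apparent viscosity at a 100 1/s reference shear rate.
    """
    props = props or series.props
    mesh = mesh or series.mesh
    mu_char = float(viscosity_field(np.array(RE_REFERENCE_SHEAR), props))
    geom = mesh.geometry
    report = {}

    def entry(name, u_peak, width):
        re = props.rho * u_peak * width / mu_char
        return {"U_peak": u_peak, "D": width, "Re": re, "laminar": re <= LAMINAR_RE_LIMIT}

    q_in_peak = max(abs(q) for q in series.log["inlet_flow"]) if series.log["t"] else 0.0
    report["inlet"] = entry("inlet", q_in_peak / geom.width, geom.width)
    names = {o.name: o for o in geom.outlets}
    peaks: dict = {}
    for flows in series.log["outlet_flows"]:
        for name, q in flows.items():
            peaks[name] = max(peaks.get(name, 0.0), abs(q))
    for name, q in peaks.items():
        width = names[name].width if names[name].side != "distal" else geom.width
        report[name] = entry(name, q / width, width)
    report["all_laminar"] = all(
        v["laminar"] for k, v in report.items() if isinstance(v, dict)
    )
    return report
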