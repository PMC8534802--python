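"""Discrete differential operators on the staggered rectilinear grid.

Shared by the flow solver and the post-processing module so that, e.g.,
the shear-rate field used for the viscosity closure and the one reported
downstream are produced by the identical operator.

Field layout (MAC staggering):
    u : (nx+1, ny)  x-velocity on x-normal faces
    v : (nx, ny+1)  y-velocity on y-normal faces
    p : (nx, ny)    cell centres
No-slip walls carry zero velocity; one-sided differences toward walls use
the half-cell distance from the first cell centre to the wall.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cell_center_velocity",
    "wall_adjacency",
    "velocity_gradients",
    "shear_rate",
    "divergence",
]


def cell_center_velocity(u: np.ndarray, v: np.ndarray):
    """Interpolate staggered face velocities to cell centres."""
    uc = 0.5 * (u[:-1, :] + u[1:, :])
    vc = 0.5 * (v[:, :-1] + v[:, 1:])
    return uc, vc


def wall_adjacency(mesh):
    """Boolean masks of no-slip faces around each cell, all (nx, ny).

    Returns ``(wall_below, wall_above, wall_left, wall_right)``.  Solid
    (flap) neighbours and tagged ``wall`` boundary faces count as walls;
    the inlet plane counts as a zero-tangential-velocity face for v;
    outlet faces are open (zero-gradient, no wall value).
    """
    nx, ny = mesh.nx, mesh.ny
    solid = ~mesh.fluid
    wall_below = np.zeros((nx, ny), bool)
    wall_above = np.zeros((nx, ny), bool)
    wall_left = np.zeros((nx, ny), bool)
    wall_right = np.zeros((nx, ny), bool)

    wall_below[:, 0] = [t == "wall" for t in mesh.bottom_tags]
    wall_above[:, -1] = [t == "wall" for t in mesh.top_tags]
    wall_left[0, :] = True  # inlet plane: tangential velocity is zero
    wall_right[-1, :] = [t == "wall" for t in mesh.right_tags]

    wall_below[:, 1:] |= solid[:, :-1]
    wall_above[:, :-1] |= solid[:, 1:]
    wall_left[1:, :] |= solid[:-1, :]
    wall_right[:-1, :] |= solid[1:, :]
    return wall_below, wall_above, wall_left, wall_right


def _cross_derivative(fc, centers, faces, wall_lo, wall_hi):
    """d(fc)/dy along axis 1 with wall-aware one-sided stencils.

    ``centers``/``faces`` are the cell-centre and face coordinates along
    axis 1.  Where a wall bounds the cell the tangential value is 0 at the
    face (half-cell distance); where no data exists (open boundary) the
    stencil degrades to one-sided or zero.
    """
    n0, n1 = fc.shape
    val_lo = np.zeros_like(fc)
    pos_lo = np.zeros_like(fc)
    has_lo = np.array(wall_lo, bool).copy()
    val_hi = np.zeros_like(fc)
    pos_hi = np.zeros_like(fc)
    has_hi = np.array(wall_hi, bool).copy()

    for j in range(n1):
        # lower neighbour: wall face beats (solid) cell data
        pos_lo[:, j] = np.where(wall_lo[:, j], faces[j], centers[j - 1] if j > 0 else 0.0)
        if j > 0:
            val_lo[:, j] = np.where(wall_lo[:, j], 0.0, fc[:, j - 1])
            has_lo[:, j] |= True
        # upper neighbour
        pos_hi[:, j] = np.where(
            wall_hi[:, j], faces[j + 1], centers[j + 1] if j < n1 - 1 else 0.0
        )
        if j < n1 - 1:
            val_hi[:, j] = np.where(wall_hi[:, j], 0.0, fc[:, j + 1])
            has_hi[:, j] |= True

    out = np.zeros_like(fc)
    yc = np.broadcast_to(centers[None, :], fc.shape)
    both = has_lo & has_hi
    out[both] = (val_hi[both] - val_lo[both]) / (pos_hi[both] - pos_lo[both])
    only_lo = has_lo & ~has_hi
    out[only_lo] = (fc[only_lo] - val_lo[only_lo]) / (yc[only_lo] - pos_lo[only_lo])
    only_hi = has_hi & ~has_lo
    out[only_hi] = (val_hi[only_hi] - fc[only_hi]) / (pos_hi[only_hi] - yc[only_hi])
    return out


def velocity_gradients(u: np.ndarray, v: np.ndarray, mesh):
    """(du/dx, du/dy, dv/dx, dv/dy) at cell centres.

    Normal derivatives (du/dx, dv/dy) come exactly from the staggered
    faces; cross derivatives use wall-aware centred differences.
    """
    dx, dy = mesh.dx, mesh.dy
    dudx = (u[1:, :] - u[:-1, :]) / dx[:, None]
    dvdy = (v[:, 1:] - v[:, :-1]) / dy[None, :]

    uc, vc = cell_center_velocity(u, v)
    wall_below, wall_above, wall_left, wall_right = wall_adjacency(mesh)
    dudy = _cross_derivative(uc, mesh.yc, mesh.yf, wall_below, wall_above)
    dvdx = _cross_derivative(vc.T, mesh.xc, mesh.xf, wall_left.T, wall_right.T).T

    solid = ~mesh.fluid
    for g in (dudx, dudy, dvdx, dvdy):
        g[solid] = 0.0
    return dudx, dudy, dvdx, dvdy


def shear_rate(u: np.ndarray, v: np.ndarray, mesh) -> np.ndarray:
    """Shear-rate magnitude gamma = sqrt(2 D:D) per cell, 1/s.

    ``D`` is the symmetric part of the velocity gradient; for simple shear
    u = (a*y, 0) this evaluates to ``a`` exactly.
    """
    dudx, dudy, dvdx, dvdy = velocity_gradients(u, v, mesh)
    return np.sqrt(2.0 * dudx**2 + 2.0 * dvdy**2 + (dudy + dvdx) ** 2)


def divergence(u: np.ndarray, v: np.ndarray, mesh) -> np.ndarray:
    """Net outward volume flux per cell (m^2/s per unit depth)."""
    dx, dy = mesh.dx, mesh.dy
    div = (u[1:, :] - u[:-1, :]) * dy[None, :] + (v[:, 1:] - v[:, :-1]) * dx[:, None]
    div[~mesh.fluid] = 0.0
    return div
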