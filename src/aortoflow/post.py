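"""Derived hemodynamic quantities: shear rate, WSS, flows, summaries.

Wall shear stress is reported as a magnitude, mu_w * |du_t/dn|, evaluated
face-by-face on every no-slip wall (channel walls and both flap faces)
with the wall viscosity taken from the Quemada closure at the wall-face
shear rate.  Flows are per-unit-depth integrals over the tagged outlet
faces; the mL/s conversion uses a configurable nominal out-of-plane depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import operators
from .rheology import BloodProperties, viscosity_field

__all__ = [
    "WSSProfile",
    "OutletFlow",
    "HemodynamicSummary",
    "shear_rate_field",
    "wss_profile",
    "wall_ids",
    "outlet_mass_flows",
    "summarize_case",
    "centerline_velocity",
]

#: nominal out-of-plane depth used to express per-unit-depth flows in mL/s
NOMINAL_DEPTH = 0.01  # m


def shear_rate_field(field, mesh) -> np.ndarray:
    """Shear-rate magnitude per cell, 1/s (same operator as the solver)."""
    return operators.shear_rate(field.u, field.v, mesh)


@dataclass(frozen=True)
class WSSProfile:
    """Wall shear stress along one wall at one instant."""

    wall_id: str
    arc_coordinate: np.ndarray  # m along the wall
    wss: np.ndarray  # Pa, magnitude
    time: float  # s

    def mean(self) -> float:
        return float(self.wss.mean()) if self.wss.size else 0.0


def _wall_faces(mesh):
    """Enumerate no-slip wall faces: (wall_id, arc, cell_idx, dist, area, comp).

    ``comp`` is "u" for horizontal walls (tangential velocity u) and "v"
    for vertical ones.  ``dist`` is the half-cell distance from the
    adjacent fluid-cell centre to the wall plane.
    """
    faces = []
    fluid = mesh.fluid
    xc, yc, xf, yf, dx, dy = mesh.xc, mesh.yc, mesh.xf, mesh.yf, mesh.dx, mesh.dy
    nx, ny = mesh.nx, mesh.ny
    for i in range(nx):
        if mesh.bottom_tags[i] == "wall" and fluid[i, 0]:
            faces.append(("wall:bottom", xc[i], (i, 0), yc[0] - yf[0], dx[i], "u"))
        if mesh.top_tags[i] == "wall" and fluid[i, ny - 1]:
            faces.append(("wall:top", xc[i], (i, ny - 1), yf[ny] - yc[ny - 1], dx[i], "u"))
    solid = ~fluid
    for i in range(nx):
        for j in range(ny):
            if not solid[i, j]:
                continue
            if j > 0 and fluid[i, j - 1]:
                faces.append(
                    ("wall:flap_lower", xc[i], (i, j - 1), yf[j] - yc[j - 1], dx[i], "u")
                )
            if j + 1 < ny and fluid[i, j + 1]:
                faces.append(
                    ("wall:flap_upper", xc[i], (i, j + 1), yc[j + 1] - yf[j + 1], dx[i], "u")
                )
            if i > 0 and fluid[i - 1, j]:
                faces.append(
                    ("wall:flap_end", yc[j], (i - 1, j), xf[i] - xc[i - 1], dy[j], "v")
                )
            if i + 1 < nx and fluid[i + 1, j]:
                faces.append(
                    ("wall:flap_end", yc[j], (i + 1, j), xc[i + 1] - xf[i + 1], dy[j], "v")
                )
    return faces


def wall_ids(mesh):
    """Wall region identifiers present on this mesh."""
    return sorted({f[0] for f in _wall_faces(mesh)})


def wss_profile(field, mesh, wall_id: str, props: Optional[BloodProperties] = None) -> WSSProfile:
    """WSS magnitude along one wall region at the snapshot's time.

    The wall viscosity comes from the rheology closure evaluated at the
    wall shear rate when ``props`` is given, otherwise from the
    snapshot's per-cell viscosity field.
    """
    faces = [f for f in _wall_faces(mesh) if f[0] == wall_id]
    if not faces:
        raise ValueError(
            f"unknown wall id {wall_id!r}; available: {wall_ids(mesh)}"
        )
    uc, vc = operators.cell_center_velocity(field.u, field.v)
    arc = np.array([f[1] for f in faces])
    order = np.argsort(arc)
    arcs, wss = [], []
    for idx in order:
        _, a, (i, j), dist, _, comp = faces[idx]
        u_t = uc[i, j] if comp == "u" else vc[i, j]
        gamma_w = abs(u_t) / dist
        if props is not None:
            mu_w = float(viscosity_field(np.array(gamma_w), props))
        else:
            mu_w = float(field.mu[i, j])
        arcs.append(a)
        wss.append(mu_w * gamma_w)
    return WSSProfile(wall_id, np.array(arcs), np.array(wss), field.t)


def _mean_wss(field, mesh, props) -> dict:
    """Area-weighted mean WSS per wall id and overall, Pa."""
    sums: dict = {}
    areas: dict = {}
    uc, vc = operators.cell_center_velocity(field.u, field.v)
    for wall_id, _, (i, j), dist, area, comp in _wall_faces(mesh):
        u_t = uc[i, j] if comp == "u" else vc[i, j]
        gamma_w = abs(u_t) / dist
        mu_w = float(viscosity_field(np.array(gamma_w), props))
        tau = mu_w * gamma_w
        sums[wall_id] = sums.get(wall_id, 0.0) + tau * area
        areas[wall_id] = areas.get(wall_id, 0.0) + area
    out = {k: sums[k] / areas[k] for k in sums}
    out["all"] = sum(sums.values()) / sum(areas.values())
    return out


@dataclass(frozen=True)
class OutletFlow:
    """Flow through one outlet (per unit depth + nominal-depth mL/s)."""

    mass_kg_per_m_s: float
    volumetric_m2_s: float
    volumetric_mL_s: float


def outlet_mass_flows(field, mesh, props, depth: float = NOMINAL_DEPTH) -> dict:
    """Mass and volumetric flow per tagged outlet from a snapshot."""
    flows: dict = {}
    fluid = mesh.fluid
    for j in range(mesh.ny):
        tag = mesh.right_tags[j]
        if tag.startswith("outlet") and fluid[-1, j]:
            flows[tag[7:]] = flows.get(tag[7:], 0.0) + field.u[-1, j] * mesh.dy[j]
    for i in range(mesh.nx):
        tag = mesh.bottom_tags[i]
        if tag.startswith("outlet") and fluid[i, 0]:
            flows[tag[7:]] = flows.get(tag[7:], 0.0) + (-field.v[i, 0]) * mesh.dx[i]
        tag = mesh.top_tags[i]
        if tag.startswith("outlet") and fluid[i, -1]:
            flows[tag[7:]] = flows.get(tag[7:], 0.0) + field.v[i, -1] * mesh.dx[i]
    return {
        name: OutletFlow(
            mass_kg_per_m_s=props.rho * q,
            volumetric_m2_s=q,
            volumetric_mL_s=q * depth * 1e6,
        )
        for name, q in flows.items()
    }


def centerline_velocity(field, mesh, x: float | None = None) -> float:
    """Peak axial velocity across the section at ``x`` (default mid-length).

    The maximum over cell centres is refined by a local quadratic fit so
    the estimate is second-order accurate even when no cell centre sits
    exactly on the channel axis.
    """
    xc = mesh.xc
    i = int(np.argmin(np.abs(xc - (x if x is not None else 0.5 * mesh.xf[-1]))))
    uc, _ = operators.cell_center_velocity(field.u, field.v)
    prof = uc[i, :]
    j = int(np.argmax(prof))
    if 0 < j < prof.size - 1:
        a, b, c = np.polyfit(mesh.yc[j - 1 : j + 2], prof[j - 1 : j + 2], 2)
        if a < 0:  # parabola vertex value
            return float(c - b**2 / (4.0 * a))
    return float(prof[j])


@dataclass(frozen=True)
class HemodynamicSummary:
    """Cycle-resolved summary of one simulated case."""

    per_outlet_flow_mL_s: dict  # cycle-mean volumetric flow per outlet
    peak_velocity: float  # m/s over retained snapshots
    peak_velocity_location: tuple  # (x, y) m
    mean_wss: dict  # Pa per wall id + "all"
    max_wss: float  # Pa
    mean_viscosity: float  # Pa*s
    max_viscosity: float  # Pa*s
    distal_mean_velocity: float  # m/s, cycle-mean distal outlet velocity
    false_lumen_flow_fraction: Optional[float]  # dissected cases only

    def as_row(self) -> dict:
        row = {
            "peak_velocity": self.peak_velocity,
            "peak_x": self.peak_velocity_location[0],
            "peak_y": self.peak_velocity_location[1],
            "max_wss": self.max_wss,
            "mean_viscosity": self.mean_viscosity,
            "max_viscosity": self.max_viscosity,
            "distal_mean_velocity": self.distal_mean_velocity,
            "false_lumen_flow_fraction": (
                np.nan
                if self.false_lumen_flow_fraction is None
                else self.false_lumen_flow_fraction
            ),
        }
        for k, v in self.mean_wss.items():
            row[f"mean_wss[{k}]"] = v
        for k, v in self.per_outlet_flow_mL_s.items():
            row[f"flow_mL_s[{k}]"] = v
        return row


def summarize_case(series, mesh, props, case=None, depth: float = NOMINAL_DEPTH) -> HemodynamicSummary:
    """Aggregate retained snapshots into a :class:`HemodynamicSummary`.

    Cycle means are taken over the retained (post-discard) snapshots;
    the false-lumen flow fraction is the cycle-mean share of axial flux
    carried above the flap at the flap's axial midpoint (dissected cases).
    """
    if not series.fields:
        raise ValueError("series holds no retained snapshots")
    geom = mesh.geometry
    dissected = geom.dissected

    flow_sums: dict = {}
    peak_v = -1.0
    peak_loc = (0.0, 0.0)
    wss_sums: dict = {}
    max_wss = 0.0
    mu_sum = 0.0
    mu_max = 0.0
    q_true = 0.0
    q_false = 0.0

    if dissected:
        y_lo, y_hi = geom.flap_y_interval()
        x_mid = 0.5 * (geom.flap.x_start + geom.flap.x_end)
        i_mid = int(np.argmin(np.abs(mesh.xc - x_mid)))

    n = len(series.fields)
    for fld in series.fields:
        flows = outlet_mass_flows(fld, mesh, props, depth)
        for name, f in flows.items():
            flow_sums[name] = flow_sums.get(name, 0.0) + f.volumetric_mL_s / n
        uc, vc = operators.cell_center_velocity(fld.u, fld.v)
        speed = np.sqrt(uc**2 + vc**2)
        speed[~mesh.fluid] = 0.0
        k = int(np.argmax(speed))
        if speed.flat[k] > peak_v:
            peak_v = float(speed.flat[k])
            i, j = np.unravel_index(k, speed.shape)
            peak_loc = (float(mesh.xc[i]), float(mesh.yc[j]))
        mw = _mean_wss(fld, mesh, props)
        for kk, vv in mw.items():
            wss_sums[kk] = wss_sums.get(kk, 0.0) + vv / n
        for wid in wall_ids(mesh):
            prof = wss_profile(fld, mesh, wid, props)
            if prof.wss.size:
                max_wss = max(max_wss, float(prof.wss.max()))
        mu = fld.mu[mesh.fluid]
        mu_sum += float(mu.mean()) / n
        mu_max = max(mu_max, float(mu.max()))
        if dissected:
            flux = fld.u[i_mid, :] * mesh.dy  # axial flux per row at x_mid
            above = mesh.yc > y_hi
            below = mesh.yc < y_lo
            q_false += max(flux[above & mesh.fluid[i_mid]].sum(), 0.0) / n
            q_true += max(flux[below & mesh.fluid[i_mid]].sum(), 0.0) / n

    distal = [o for o in geom.outlets if o.side == "distal"]
    distal_v = 0.0
    if distal:
        q = flow_sums.get(distal[0].name, 0.0) / (depth * 1e6)  # back to m^2/s
        distal_v = q / geom.width

    frac = None
    if dissected:
        tot = q_true + q_false
        frac = float(min(max(q_false / tot, 0.0), 1.0)) if tot > 0 else 0.0

    return HemodynamicSummary(
        per_outlet_flow_mL_s=flow_sums,
        peak_velocity=peak_v,
        peak_velocity_location=peak_loc,
        mean_wss=wss_sums,
        max_wss=max_wss,
        mean_viscosity=mu_sum,
        max_viscosity=mu_max,
        distal_mean_velocity=distal_v,
        false_lumen_flow_fraction=frac,
    )


def false_lumen_flow_fraction(summary: HemodynamicSummary) -> float:
    """Accessor that insists the case was dissected."""
    if summary.false_lumen_flow_fraction is None:
        raise ValueError("false-lumen flow split is undefined for a non-dissected case")
    return summary.false_lumen_flow_fraction
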