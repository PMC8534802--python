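#!/usr/bin/env python
"""Stage 2 — flow-solver verification against the analytic channel.

Solves steady Newtonian plane-channel flow at Re ~ 100 on a coarse and a
refined grid and compares the centerline velocity (1.5 x mean) and wall
shear stress (6 mu U / h) with the analytic Poiseuille solution, then
runs the mesh-independence sweep on the study geometry.  Writes
results/solver_verification.csv and results/mesh_independence.csv.

Finding to look for: centerline within 2% and WSS within 3% on the
default grid, both errors shrinking under refinement.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from aortoflow import post  # noqa: E402
from aortoflow.geometry import Outlet, VesselGeometry  # noqa: E402
from aortoflow.meshing import mesh_geometry, mesh_independence  # noqa: E402
from aortoflow.pipeline import CaseSpec  # noqa: E402
from aortoflow.rheology import BloodProperties  # noqa: E402
from aortoflow.solver import ProjectionSolver  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
MU, H, L = 3.5e-3, 0.02, 0.1


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    geom = VesselGeometry(length=L, width=H, outlets=(Outlet("out", "distal", L, H),))
    props = BloodProperties(mu_p=MU, hct=0.0)
    u_mean = 100.0 * MU / (props.rho * H)
    analytic_wss = 6.0 * MU * u_mean / H

    rows = []
    for bulk in (2e-3, 1e-3):
        mesh = mesh_geometry(geom, bulk_size=bulk, first_layer=1e-4)
        field = ProjectionSolver.steady(mesh, props, u_mean, profile="parabolic").solve_steady()
        center = post.centerline_velocity(field, mesh)
        prof = post.wss_profile(field, mesh, "wall:bottom", props)
        wss = float(prof.wss[prof.arc_coordinate > L / 2].mean())
        rows.append(
            {
                "bulk_size_m": bulk,
                "n_cells": mesh.n_cells,
                "centerline_m_s": center,
                "centerline_err_pct": 100 * abs(center / (1.5 * u_mean) - 1),
                "wss_Pa": wss,
                "wss_err_pct": 100 * abs(wss / analytic_wss - 1),
            }
        )
        print(
            f"bulk {bulk * 1e3:.1f} mm: centerline err "
            f"{rows[-1]['centerline_err_pct']:.3f}%, WSS err {rows[-1]['wss_err_pct']:.3f}%"
        )
    pd.DataFrame(rows).to_csv(os.path.join(RESULTS, "solver_verification.csv"), index=False)

    case = CaseSpec(dissected=False, hct=0.40, intensity="real")
    sweep = mesh_independence(case, [4e-3, 2e-3])
    pd.DataFrame(sweep).to_csv(os.path.join(RESULTS, "mesh_independence.csv"), index=False)
    print("mesh independence:", [
        (r["bulk_size"], r["converged"], round(r["peak_wss"], 4)) for r in sweep
    ])


if __name__ == "__main__":
    main()
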