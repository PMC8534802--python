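"""End-to-end orchestration of the 8-case factorial experiment.

The design crosses three factors — wall configuration (dissected vs.
repaired), hematocrit (0.40 vs. 0.50) and inlet intensity (real vs.
high) — into eight cases sharing one geometry outline and one waveform
family, so differences between cases isolate the factor effects.  Each
case runs the multi-cycle pulsatile protocol (first cycles discarded),
is summarized by the post-processing module, and the cross-case sign
tables plus a Bland–Altman verification against pseudo-Doppler flows
form the consolidated report.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dfield, asdict
from itertools import product
from typing import Optional

import numpy as np

from . import post
from .geometry import build_geometry, default_geometry_params
from .imaging import (
    compare_masks,
    fill_holes,
    image_quality,
    region_grow,
    robust_seed_point,
)
from .meshing import mesh_geometry
from .rheology import BloodProperties
from .solver import BoundaryConditions, ProjectionSolver
from .stats import bland_altman
from .synthetic import PhantomSpec, generate_phantom, generate_inlet_waveform

__all__ = [
    "CaseSpec",
    "default_cases",
    "case_geometry",
    "case_blood",
    "case_waveform",
    "run_case",
    "tear_wss_ratio",
    "sign_tables",
    "run_experiment",
    "run_qc",
]

#: time-averaged inlet velocity of the measured ("real") waveform, m/s
DEFAULT_MEAN_VELOCITY = 0.06


@dataclass(frozen=True)
class CaseSpec:
    """One cell of the factorial design plus its numerical settings."""

    dissected: bool
    hct: float
    intensity: str  # "real" | "high"
    mean_velocity: float = DEFAULT_MEAN_VELOCITY
    period: float = 1.0
    n_cycles: int = 5
    discard: int = 3
    bulk_size: float = 2.0e-3
    first_layer: float = 2.5e-4
    expansion_ratio: float = 1.15
    n_boundary_layers: int = 5
    steps_per_cycle: Optional[int] = None
    snapshots_per_cycle: int = 25
    form: str = "printed"
    seed: int = 0
    geometry_params: Optional[dict] = None
    # branch outlets sit at a slightly lower gauge pressure than the
    # distal outlet so they carry a physiological share of the flow
    outlet_pressures: Optional[dict] = dfield(
        default_factory=lambda: {"Visceral": -1.5, "Renal_1": -1.5}
    )

    @property
    def name(self) -> str:
        wall = "dissected" if self.dissected else "repaired"
        return f"{wall}_hct{int(round(self.hct * 100))}_{self.intensity}"


def default_cases(seed: int = 0, **overrides) -> list:
    """The eight (wall x hematocrit x intensity) cases."""
    cases = []
    for dissected, hct, intensity in product(
        (True, False), (0.40, 0.50), ("real", "high")
    ):
        cases.append(
            CaseSpec(dissected=dissected, hct=hct, intensity=intensity, seed=seed, **overrides)
        )
    return cases


def case_geometry(case: CaseSpec):
    return build_geometry(case.dissected, case.geometry_params)


def case_blood(case: CaseSpec) -> BloodProperties:
    return BloodProperties(hct=case.hct, form=case.form)


def case_waveform(case: CaseSpec):
    return generate_inlet_waveform(
        case.intensity, case.mean_velocity, case.period, seed=case.seed
    )


def run_case(case: CaseSpec):
    """Mesh, solve and summarize one case.

    Returns ``(series, mesh, props, summary)``.
    """
    geom = case_geometry(case)
    mesh = mesh_geometry(
        geom,
        bulk_size=case.bulk_size,
        first_layer=case.first_layer,
        ratio=case.expansion_ratio,
        n_boundary_layers=case.n_boundary_layers,
    )
    props = case_blood(case)
    bc = BoundaryConditions(
        inlet=case_waveform(case),
        inlet_profile="plug",
        outlet_pressures=case.outlet_pressures,
    )
    solver = ProjectionSolver(mesh, props, bc)
    series = solver.run_cycles(
        case.n_cycles,
        discard=case.discard,
        steps_per_cycle=case.steps_per_cycle,
        snapshots_per_cycle=case.snapshots_per_cycle,
    )
    summary = post.summarize_case(series, mesh, props, case)
    return series, mesh, props, summary


def tear_wss_ratio(series, mesh, props, near_gap_lengths: float = 1.0,
                   far_gap_lengths: float = 3.0) -> float:
    """Peak-systole WSS near the tears vs. the remote-wall median.

    Ratio of the maximum WSS within ``near_gap_lengths`` tear lengths of
    any tear edge to the median WSS on wall faces farther than
    ``far_gap_lengths`` tear lengths from every tear, evaluated at the
    retained snapshot with the highest inlet velocity (peak systole).
    """
    geom = mesh.geometry
    if not geom.dissected:
        raise ValueError("tear-adjacent WSS requires a dissected geometry")
    q = [abs(f.u[0, :] @ mesh.dy) for f in series.fields]
    fld = series.fields[int(np.argmax(q))]
    tears = [t for t in geom.flap.tears]
    gap = max(t.length for t in tears)
    near_vals, far_vals = [], []
    for wid in post.wall_ids(mesh):
        prof = post.wss_profile(fld, mesh, wid, props)
        if wid == "wall:flap_end":
            near_vals.extend(prof.wss)  # tear faces themselves
            continue
        for a, w in zip(prof.arc_coordinate, prof.wss):
            d = min(
                min(abs(a - t.x_interval[0]), abs(a - t.x_interval[1]))
                if not (t.x_interval[0] <= a <= t.x_interval[1])
                else 0.0
                for t in tears
            )
            if d <= near_gap_lengths * gap:
                near_vals.append(w)
            elif d >= far_gap_lengths * gap:
                far_vals.append(w)
    if not near_vals or not far_vals:
        raise ValueError("insufficient wall faces for the tear/remote split")
    return float(np.max(near_vals) / max(np.median(far_vals), 1e-30))


def sign_tables(summaries: dict) -> dict:
    """Cross-case factor-effect signs from per-case summaries.

    ``summaries`` maps case name -> HemodynamicSummary.  Returns, per
    matched pair, the differences whose signs mirror the study's
    directional findings.
    """

    def get(dissected, hct, intensity):
        wall = "dissected" if dissected else "repaired"
        return summaries[f"{wall}_hct{int(round(hct * 100))}_{intensity}"]

    table = {"dissection": [], "hematocrit": [], "intensity": []}
    for hct, intensity in product((0.40, 0.50), ("real", "high")):
        d, r = get(True, hct, intensity), get(False, hct, intensity)
        table["dissection"].append(
            {
                "hct": hct,
                "intensity": intensity,
                "delta_distal_velocity": d.distal_mean_velocity - r.distal_mean_velocity,
                "delta_mean_wss": d.mean_wss["all"] - r.mean_wss["all"],
            }
        )
    for dissected, intensity in product((True, False), ("real", "high")):
        hi, lo = get(dissected, 0.50, intensity), get(dissected, 0.40, intensity)
        table["hematocrit"].append(
            {
                "dissected": dissected,
                "intensity": intensity,
                "delta_mean_viscosity": hi.mean_viscosity - lo.mean_viscosity,
                "delta_mean_wss": hi.mean_wss["all"] - lo.mean_wss["all"],
            }
        )
    for dissected, hct in product((True, False), (0.40, 0.50)):
        h, r = get(dissected, hct, "high"), get(dissected, hct, "real")
        table["intensity"].append(
            {
                "dissected": dissected,
                "hct": hct,
                "delta_peak_velocity": h.peak_velocity - r.peak_velocity,
            }
        )
    return table


def _pseudo_doppler(cfd_flows, bias: float, sd: float, seed: int):
    rng = np.random.default_rng(seed)
    cfd = np.asarray(cfd_flows, dtype=float)
    return cfd + bias + rng.normal(0.0, sd, size=cfd.shape)


def run_experiment(
    outdir,
    cases: Optional[list] = None,
    seed: int = 0,
    doppler_bias: float = 0.0,
    doppler_sd: float = 0.05,
    resume: bool = True,
    case_overrides: Optional[dict] = None,
) -> dict:
    """Run the factorial, write per-case results + consolidated report.

    Re-entrant: finished cases (summary JSON already on disk) are loaded
    instead of recomputed when ``resume``.  Every parameter and seed is
    written to ``manifest.json`` so reports are self-describing.
    """
    os.makedirs(outdir, exist_ok=True)
    if cases is None:
        cases = default_cases(seed=seed, **(case_overrides or {}))

    manifest = {
        "seed": seed,
        "doppler_bias": doppler_bias,
        "doppler_sd": doppler_sd,
        "geometry_defaults": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in default_geometry_params().items()
        },
        "cases": [asdict(c) for c in cases],
    }

    summaries: dict = {}
    reports: dict = {"cases": {}}
    for case in cases:
        case_dir = os.path.join(outdir, case.name)
        os.makedirs(case_dir, exist_ok=True)
        summary_path = os.path.join(case_dir, "summary.json")
        if resume and os.path.exists(summary_path):
            with open(summary_path) as fh:
                row = json.load(fh)
            reports["cases"][case.name] = row
            summaries[case.name] = _summary_from_row(row)
            continue
        try:
            series, mesh, props, summary = run_case(case)
        except Exception as exc:  # recorded, not raised: partial reports
            reports["cases"][case.name] = {"failed": True, "error": str(exc)}
            continue
        row = summary.as_row()
        row["cycle_metrics"] = list(map(float, series.cycle_metrics))
        row["max_rel_divergence"] = float(max(series.log["max_rel_div"]))
        row["max_mass_imbalance"] = float(max(series.log["mass_imbalance"]))
        if case.dissected:
            row["tear_wss_ratio"] = tear_wss_ratio(series, mesh, props)
        with open(summary_path, "w") as fh:
            json.dump(row, fh, indent=1, sort_keys=True)
        _write_case_outputs(case_dir, series, mesh, props)
        reports["cases"][case.name] = row
        summaries[case.name] = summary

    complete = all(not r.get("failed") for r in reports["cases"].values())
    reports["complete"] = complete
    full_design = {c.name for c in default_cases()}
    if complete and len(summaries) == len(cases):
        if full_design <= set(summaries):
            reports["signs"] = sign_tables(summaries)
        cfd = []
        for name in sorted(summaries):
            cfd.extend(summaries[name].per_outlet_flow_mL_s.values())
        doppler = _pseudo_doppler(cfd, doppler_bias, doppler_sd, seed + 1)
        reports["bland_altman_vs_doppler"] = bland_altman(
            np.asarray(cfd), doppler
        ).as_dict()

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(reports, fh, indent=1, sort_keys=True)
    return reports


def _summary_from_row(row: dict) -> post.HemodynamicSummary:
    """Rebuild the summary object from a persisted case row (resume path)."""
    mean_wss = {
        k[len("mean_wss[") : -1]: v for k, v in row.items() if k.startswith("mean_wss[")
    }
    flows = {
        k[len("flow_mL_s[") : -1]: v for k, v in row.items() if k.startswith("flow_mL_s[")
    }
    fl = row.get("false_lumen_flow_fraction")
    return post.HemodynamicSummary(
        per_outlet_flow_mL_s=flows,
        peak_velocity=row["peak_velocity"],
        peak_velocity_location=(row["peak_x"], row["peak_y"]),
        mean_wss=mean_wss,
        max_wss=row["max_wss"],
        mean_viscosity=row["mean_viscosity"],
        max_viscosity=row["max_viscosity"],
        distal_mean_velocity=row["distal_mean_velocity"],
        false_lumen_flow_fraction=None if fl is None or np.isnan(fl) else fl,
    )


def _write_case_outputs(case_dir, series, mesh, props) -> None:
    """WSS profiles + a peak-systole field snapshot, as CSV/VTK."""
    import pandas as pd

    from .io import write_vtk_quads

    q = [abs(f.u[0, :] @ mesh.dy) for f in series.fields]
    fld = series.fields[int(np.argmax(q))]
    rows = []
    for wid in post.wall_ids(mesh):
        prof = post.wss_profile(fld, mesh, wid, props)
        for a, w in zip(prof.arc_coordinate, prof.wss):
            rows.append({"wall": wid, "arc_m": a, "wss_Pa": w, "t_s": prof.time})
    pd.DataFrame(rows).to_csv(os.path.join(case_dir, "wss_profiles.csv"), index=False)

    from . import operators

    uc, vc = operators.cell_center_velocity(fld.u, fld.v)
    gamma = post.shear_rate_field(fld, mesh)
    write_vtk_quads(
        mesh,
        os.path.join(case_dir, "field_peak_systole.vtk"),
        {
            "u": uc,
            "v": vc,
            "p": fld.p,
            "viscosity": fld.mu,
            "shear_rate": gamma,
        },
    )


# --------------------------------------------------------------------------
# imaging QC pipeline
# --------------------------------------------------------------------------


def default_tolerance(spec: PhantomSpec) -> float:
    """Half the object-background contrast: the window edge sits midway."""
    return 0.5 * (spec.object_intensity - spec.background_intensity)


def run_qc(
    n_phantoms: int = 10,
    base_seed: int = 1,
    tolerance: Optional[float] = None,
    phantom_overrides: Optional[dict] = None,
) -> dict:
    """Generate, segment and score ``n_phantoms`` phantoms.

    Per phantom: region growing from a median-matched central seed inside
    a +/- tolerance window (default: half-contrast rule), per-slice hole
    filling, then volume error and Dice against the generator's ground
    truth, plus the ROI image-quality metrics.
    """
    rows = []
    for k in range(n_phantoms):
        spec = PhantomSpec(seed=base_seed + k, **(phantom_overrides or {}))
        tol = default_tolerance(spec) if tolerance is None else tolerance
        volume, truth = generate_phantom(spec)
        seed_pt = robust_seed_point(volume)
        mask = fill_holes(region_grow(volume, seed_pt, tol))
        if not mask.voxels.any():
            rows.append({"seed": spec.seed, "failed": True})
            continue
        err, dice = compare_masks(mask, truth)
        iq = image_quality(volume)
        rows.append(
            {
                "seed": spec.seed,
                "failed": False,
                "volume_error_pct": err,
                "dice": dice,
                "noise": iq.noise,
                "bi": iq.bi,
                "cnr": iq.cnr,
                "tolerance": tol,
            }
        )
    ok = [r for r in rows if not r["failed"]]
    return {
        "per_phantom": rows,
        "n_failed": sum(r["failed"] for r in rows),
        "max_volume_error_pct": max((r["volume_error_pct"] for r in ok), default=np.nan),
        "median_volume_error_pct": float(
            np.median([r["volume_error_pct"] for r in ok])
        )
        if ok
        else np.nan,
        "mean_cnr": float(np.mean([r["cnr"] for r in ok])) if ok else np.nan,
        "mean_bi": float(np.mean([r["bi"] for r in ok])) if ok else np.nan,
    }
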