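"""File export helpers: image stacks, waveform CSV, legacy-VTK fields.

The mesh/field writer emits the legacy ASCII VTK unstructured-grid
format (readable by ParaView and friends); no installed package writes
2-D quad meshes, so the few dozen lines live here.
"""

from __future__ import annotations

import os

import numpy as np

__all__ = [
    "save_phantom",
    "waveform_to_csv",
    "write_vtk_quads",
]


def save_phantom(volume, mask, outdir, stem: str = "phantom") -> dict:
    """Write a phantom volume as a PNG slice stack + .npy, mask likewise."""
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    paths = {"volume_npy": os.path.join(outdir, f"{stem}_volume.npy"),
             "mask_npy": os.path.join(outdir, f"{stem}_mask.npy")}
    np.save(paths["volume_npy"], volume.voxels)
    np.save(paths["mask_npy"], mask.voxels)
    stack_dir = os.path.join(outdir, f"{stem}_slices")
    os.makedirs(stack_dir, exist_ok=True)
    lo, hi = volume.voxels.min(), volume.voxels.max()
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    for k in range(volume.shape[2]):
        img = ((volume.voxels[:, :, k] - lo) * scale).astype(np.uint8)
        iio.imwrite(os.path.join(stack_dir, f"{stem}_{k:04d}.png"), img)
        iio.imwrite(
            os.path.join(stack_dir, f"{stem}_mask_{k:04d}.png"),
            (mask.voxels[:, :, k].astype(np.uint8) * 255),
        )
    paths["slices"] = stack_dir
    return paths


def waveform_to_csv(waveform, path) -> None:
    """Two-column CSV: time_s, velocity_m_per_s."""
    arr = np.column_stack([waveform.time_samples, waveform.velocity_samples])
    np.savetxt(path, arr, delimiter=",", header="time_s,velocity_m_per_s", comments="")


def write_vtk_quads(mesh, path, cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid of the fluid cells.

    ``cell_data`` maps names to (nx, ny) arrays; values are emitted for
    fluid cells in the mesh's cell ordering.
    """
    nodes = mesh.nodes
    cells = mesh.cells
    fluid_idx = np.argwhere(mesh.fluid)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\naortoflow field\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for x, y in nodes:
            fh.write(f"{x:.9g} {y:.9g} 0\n")
        fh.write(f"\nCELLS {len(cells)} {len(cells) * 5}\n")
        for quad in cells:
            fh.write("4 " + " ".join(str(n) for n in quad) + "\n")
        fh.write(f"\nCELL_TYPES {len(cells)}\n")
        fh.write("\n".join(["9"] * len(cells)) + "\n")
        if cell_data:
            fh.write(f"\nCELL_DATA {len(cells)}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                vals = [arr[i, j] for i, j in fluid_idx]
                fh.write("\n".join(f"{v:.9g}" for v in vals) + "\n")
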