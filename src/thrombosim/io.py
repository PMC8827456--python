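"""Export helpers: legacy-ASCII VTK, HDF5 snapshots, CSV metrics.

VTK output uses the legacy STRUCTURED_POINTS text format (readable by
ParaView/VisIt) so no VTK library dependency is needed.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "write_vtk_scalars",
    "write_metrics_csv",
    "write_platelets_h5",
    "write_fields_h5",
    "write_manifest",
]


def write_vtk_scalars(path, h: float, scalars: dict, vectors: dict | None = None) -> None:
    """Write voxel fields to a legacy ASCII VTK structured-points file.

    ``scalars``/``vectors`` map names to (nx, ny, nz[, 3]) arrays; spacing
    ``h`` in um.
    """
    first = next(iter(scalars.values()))
    nx, ny, nz = first.shape[:3]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nthrombosim output\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {h / 2} {h / 2} {h / 2}\n")
        f.write(f"SPACING {h} {h} {h}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in scalars.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
            np.savetxt(f, flat[:, None], fmt="%.6g")
        for name, arr in (vectors or {}).items():
            f.write(f"VECTORS {name} float\n")
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0, 3).reshape(-1, 3)
            np.savetxt(f, flat, fmt="%.6g")


def write_metrics_csv(path, result) -> None:
    """Metric time series of a SimulationResult to CSV."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["t_s", "bound_platelets", "mobile_platelets", "Q_uL_min",
                    "film_thrombin_nM", "injected", "exited", "discarded"])
        for row in zip(result.times, result.platelet_count, result.mobile_count,
                       result.Q, result.thrombin, result.injected, result.exited,
                       result.discarded):
            w.writerow([f"{row[0]:.3f}", row[1], row[2], f"{row[3]:.6g}",
                        f"{row[4]:.6g}", row[5], row[6], row[7]])


def write_platelets_h5(path, result) -> None:
    """Final platelet snapshot (positions, mobility, activation) to HDF5."""
    snap = result.final_snapshot
    with h5py.File(path, "w") as f:
        f.attrs["h_um"] = result.domain.h
        f.attrs["t_s"] = float(result.times[-1]) if len(result.times) else 0.0
        n = len(snap)
        f.create_dataset("voxel", data=np.array([p.voxel for p in snap],
                                                dtype=np.int32).reshape(n, 3))
        f.create_dataset("bound", data=np.array([p.mobility == "bound" for p in snap]))
        f.create_dataset("xi", data=np.array([p.xi for p in snap]))
        f.create_dataset("released", data=np.array([p.release_triggered for p in snap]))


def write_fields_h5(path, result) -> None:
    """Concentration fields and clot mask to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["h_um"] = result.domain.h
        f.create_dataset("bound_mask", data=result.bound_mask)
        if result.fields is not None:
            for j, arr in result.fields.C.items():
                f.create_dataset(f"C_{j}", data=arr)


def write_manifest(path, result) -> None:
    """Run manifest (config, seed, metrics summary) as JSON."""
    cfg = result.config.to_dict()
    manifest = {
        "config": _jsonable(cfg),
        "seed": result.config.seed,
        "Q0_uL_min": result.Q0,
        "final_bound": int(result.platelet_count[-1]) if len(result.platelet_count) else 0,
        "occlusion_time_s": result.occlusion_time,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
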