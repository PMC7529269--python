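"""Artifact storage: HDF5 snapshots, legacy-ASCII VTK fields, CSV traces."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .fom import SnapshotSet
from .grids import Grid2D
from .ionic import potential_to_mv, time_to_ms


def save_snapshots(path: str | Path, snapshots: SnapshotSet,
                   manifest: dict | None = None) -> None:
    """Write a snapshot set to HDF5 (/snapshots, /times, /params, /meta)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("snapshots", data=snapshots.S, dtype="float64")
        f.create_dataset("times", data=snapshots.times)
        f.create_dataset("params", data=snapshots.params)
        f.create_dataset("mu_list", data=snapshots.mu_list)
        if snapshots.F is not None:
            f.create_dataset("ionic_snapshots", data=snapshots.F)
        if snapshots.W is not None:
            f.create_dataset("gating_snapshots", data=snapshots.W)
        f.attrs["n_times"] = snapshots.n_times
        meta = {k: v for k, v in snapshots.meta.items()
                if not isinstance(v, np.ndarray)}
        if manifest:
            meta["manifest"] = manifest
        f.attrs["meta"] = json.dumps(meta)


def load_snapshots(path: str | Path) -> SnapshotSet:
    with h5py.File(path, "r") as f:
        return SnapshotSet(
            S=f["snapshots"][...],
            times=f["times"][...],
            params=f["params"][...],
            mu_list=f["mu_list"][...],
            n_times=int(f.attrs["n_times"]),
            meta=json.loads(f.attrs["meta"]),
            F=f["ionic_snapshots"][...] if "ionic_snapshots" in f else None,
            W=f["gating_snapshots"][...] if "gating_snapshots" in f else None,
        )


def write_vtk(path: str | Path, grid: Grid2D, fields: dict[str, np.ndarray],
              title: str = "cardiorom field") -> None:
    """Write nodal scalar fields as a legacy-ASCII VTK structured-points file."""
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {grid.nx} {grid.ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {grid.hx:.10g} {grid.hy:.10g} 1",
        f"POINT_DATA {grid.n_nodes}",
    ]
    for name, values in fields.items():
        values = np.asarray(values, dtype=float).ravel()
        if len(values) != grid.n_nodes:
            raise ValueError(f"field {name!r} has wrong length")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" for v in values)
    Path(path).write_text("\n".join(lines) + "\n")


def export_field_series(outdir: str | Path, grid: Grid2D, U: np.ndarray,
                        times: np.ndarray, prefix: str = "u") -> list[Path]:
    """One VTK file per sampled time, with dimensionless and mV fields."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, t in enumerate(times):
        p = outdir / f"{prefix}_{j:05d}.vtk"
        write_vtk(
            p,
            grid,
            {"u": U[:, j], "u_mV": potential_to_mv(U[:, j])},
            title=f"t = {float(time_to_ms(t)):.4f} ms",
        )
        paths.append(p)
    return paths


def save_probe_traces(path: str | Path, times: np.ndarray,
                      traces: np.ndarray, labels: list[str] | None = None
                      ) -> None:
    """CSV with t_ms and one u_mV column per probe point."""
    labels = labels or [f"probe{i}" for i in range(traces.shape[0])]
    df = pd.DataFrame({"t_ms": time_to_ms(times)})
    for lab, row in zip(labels, traces):
        df[f"u_mV_{lab}"] = potential_to_mv(row)
    df.to_csv(path, index=False)
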