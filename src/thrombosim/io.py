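"""Output writers: VTK legacy structured grids, array archives, CSV series.

Snapshots go to ASCII VTK ``STRUCTURED_POINTS`` files loadable by standard
viewers, or to a single ``.npz`` archive that round-trips the bundle
exactly.  The configuration used is always echoed verbatim alongside the
results for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .mesh import BoundaryPatch, StructuredMesh
from .scenario import OutputBundle, SimulationConfig, clot_metrics

__all__ = [
    "write_outputs",
    "write_vtk_snapshot",
    "save_bundle_archive",
    "load_bundle_archive",
    "write_config",
    "read_config",
]


def write_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path: str | Path) -> SimulationConfig:
    return SimulationConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def write_vtk_snapshot(
    mesh: StructuredMesh,
    fields: dict[str, np.ndarray],
    path: str | Path,
    title: str = "thrombosim snapshot",
) -> None:
    """ASCII VTK legacy STRUCTURED_POINTS file with cell data.

    Requires a uniform mesh (all shipped cases are uniform).  Staggered
    velocity components are written averaged to cell centers.
    """
    if not mesh.is_uniform:
        raise ValueError("VTK structured-points output requires a uniform mesh")
    ny, nx = mesh.shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 2",
        f"ORIGIN {mesh.x_faces[0]:.9g} {mesh.y_faces[0]:.9g} 0",
        f"SPACING {mesh.dx[0]:.9g} {mesh.dy[0]:.9g} 1",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape == (ny, nx + 1):      # x-face (u) data → cell centers
            arr = 0.5 * (arr[:, :-1] + arr[:, 1:])
        elif arr.shape == (ny + 1, nx):    # y-face (v) data → cell centers
            arr = 0.5 * (arr[:-1, :] + arr[1:, :])
        if arr.shape != (ny, nx):
            raise ValueError(f"field {name!r} has incompatible shape {arr.shape}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def save_bundle_archive(bundle: OutputBundle, path: str | Path) -> None:
    """Lossless ``.npz`` archive of snapshots, series and mesh geometry."""
    payload: dict[str, np.ndarray] = {
        "times": np.asarray(bundle.times),
        "x_faces": bundle.mesh.x_faces,
        "y_faces": bundle.mesh.y_faces,
    }
    for name, snaps in bundle.snapshots.items():
        payload[f"snap_{name}"] = np.stack(snaps)
    for name, vals in bundle.series.items():
        payload[f"series_{name}"] = np.asarray(vals)
    patches = [
        {"name": p.name, "type_tag": p.type_tag, "faces": [list(f) for f in p.faces]}
        for p in bundle.mesh.patches
    ]
    payload["meta_json"] = np.array(
        json.dumps({"config": bundle.config.to_dict(), "patches": patches})
    )
    np.savez(path, **payload)


def load_bundle_archive(path: str | Path) -> OutputBundle:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        patches = [
            BoundaryPatch(name=p["name"], type_tag=p["type_tag"],
                          faces=[(s, int(k)) for s, k in p["faces"]])
            for p in meta["patches"]
        ]
        mesh = StructuredMesh(x_faces=z["x_faces"], y_faces=z["y_faces"], patches=patches)
        bundle = OutputBundle(mesh=mesh, config=SimulationConfig.from_dict(meta["config"]))
        bundle.times = [float(t) for t in z["times"]]
        for key in z.files:
            if key.startswith("snap_"):
                bundle.snapshots[key[5:]] = [a for a in z[key]]
            elif key.startswith("series_"):
                bundle.series[key[7:]] = [float(v) for v in z[key]]
    return bundle


def write_outputs(
    bundle: OutputBundle,
    out_dir: str | Path,
    fmt: str = "vtk",
) -> list[Path]:
    """Write a bundle to disk: field snapshots (``vtk`` or ``archive``),
    the metric time series as CSV, and the exact configuration used."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    write_config(bundle.config, out / "config.yaml")
    written.append(out / "config.yaml")

    df = bundle.series_frame()
    df.to_csv(out / "series.csv", index=False)
    written.append(out / "series.csv")
    try:
        clot_metrics(bundle).to_csv(out / "metrics.csv", index=False)
        written.append(out / "metrics.csv")
    except ValueError:
        pass  # bundle without the clot fields

    if fmt == "vtk":
        for i, t in enumerate(bundle.times):
            fields = {k: v[i] for k, v in bundle.snapshots.items()}
            p = out / f"snapshot_{i:04d}_t{t:.3f}.vtk"
            write_vtk_snapshot(bundle.mesh, fields, p, title=f"t = {t} s")
            written.append(p)
    elif fmt == "archive":
        p = out / "bundle.npz"
        save_bundle_archive(bundle, p)
        written.append(p)
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return written
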