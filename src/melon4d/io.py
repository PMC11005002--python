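"""Snapshot serialization, VTK export, and the high-level run driver.

Native snapshot container: one compressed NPZ per snapshot (lossless
float64 fields) plus a JSON manifest recording time, step, the energy
breakdown, the config hash and the rng seed — enough to reproduce the
run exactly.  A ``.incomplete`` marker guards against partial writes:
it is created before writing and removed after, and readers refuse
marked files.

Optional VTK image-data (``.vti``) export writes one scalar array per
field with correct spacing/origin metadata for external 3D viewers
(ASCII-encoded XML; no VTK library required).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np

from .config import RunConfig
from .dynamics import Trajectory, run
from .geometry import seed_initial_state
from .model import EnergyBreakdown, FieldState

__all__ = ["write_snapshot", "read_snapshot", "write_vti",
           "run_from_config", "SnapshotError"]


class SnapshotError(RuntimeError):
    """A snapshot file is missing, incomplete, or malformed."""


def write_snapshot(fields: FieldState, path, manifest: Optional[dict] = None,
                   formats: Iterable[str] = ("npz",)) -> Dict[str, Path]:
    """Write one snapshot losslessly; returns the files written.

    ``path`` is the stem — ``<stem>.npz`` (and optionally ``<stem>.vti``)
    plus ``<stem>.manifest.json`` are created.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    marker = stem.with_suffix(".incomplete")
    marker.touch()
    written: Dict[str, Path] = {}
    try:
        if "npz" in formats:
            npz = stem.with_suffix(".npz")
            np.savez_compressed(npz, phi=fields.phi, psi1=fields.psi1,
                                psi2=fields.psi2, eta=fields.eta,
                                time=np.float64(fields.time))
            written["npz"] = npz
        if "vti" in formats:
            written["vti"] = stem.with_suffix(".vti")
        if manifest is not None:
            mpath = stem.with_suffix(".manifest.json")
            mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            written["manifest"] = mpath
    except OSError:
        # leave the marker in place: readers will refuse the partial file
        raise
    else:
        marker.unlink()
    return written


def read_snapshot(path) -> FieldState:
    """Read a snapshot written by :func:`write_snapshot` (bitwise faithful)."""
    npz = Path(path)
    if npz.suffix != ".npz":
        npz = npz.with_suffix(".npz")
    if npz.with_suffix(".incomplete").exists():
        raise SnapshotError(f"{npz} is marked incomplete; refusing to read")
    if not npz.exists():
        raise SnapshotError(f"snapshot not found: {npz}")
    with np.load(npz) as data:
        return FieldState(phi=data["phi"], psi1=data["psi1"],
                          psi2=data["psi2"], eta=data["eta"],
                          time=float(data["time"]))


def write_vti(path, fields: Dict[str, np.ndarray],
              spacing, origin=(0.0, 0.0, 0.0)) -> Path:
    """Minimal VTK XML ImageData writer (ASCII point data, one array per field).

    Field arrays are indexed ``[x, y, z]``; VTK expects x varying
    fastest, which Fortran-order raveling provides.
    """
    path = Path(path)
    arrays = {k: np.asarray(v) for k, v in fields.items()}
    shapes = {v.shape for v in arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"all fields must share one shape, got {shapes}")
    nx, ny, nz = shapes.pop()
    extent = f"0 {nx - 1} 0 {ny - 1} 0 {nz - 1}"
    sp = " ".join(f"{s:.9g}" for s in spacing)
    org = " ".join(f"{o:.9g}" for o in origin)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="ImageData" version="1.0" byte_order="LittleEndian">',
        f'  <ImageData WholeExtent="{extent}" Origin="{org}" Spacing="{sp}">',
        f'    <Piece Extent="{extent}">',
        '      <PointData Scalars="%s">' % next(iter(arrays)),
    ]
    for name, arr in arrays.items():
        flat = arr.ravel(order="F")
        lines.append(f'        <DataArray type="Float64" Name="{name}" '
                     'format="ascii">')
        # chunk the numbers to keep line lengths sane
        for i in range(0, flat.size, 9):
            lines.append("          " + " ".join(
                f"{v:.9g}" for v in flat[i:i + 9]))
        lines.append('        </DataArray>')
    lines += ['      </PointData>', '    </Piece>', '  </ImageData>',
              '</VTKFile>', '']
    path.write_text("\n".join(lines))
    return path


def read_vti_metadata(path) -> dict:
    """Spacing/origin/extent of a .vti file (for round-trip checks)."""
    import xml.etree.ElementTree as ET
    root = ET.parse(Path(path)).getroot()
    img = root.find("ImageData")
    return {
        "spacing": tuple(float(v) for v in img.attrib["Spacing"].split()),
        "origin": tuple(float(v) for v in img.attrib["Origin"].split()),
        "extent": tuple(int(v) for v in img.attrib["WholeExtent"].split()),
    }


def run_from_config(cfg: RunConfig,
                    output_dir: Optional[Path] = None) -> Trajectory:
    """Seed the initial state and integrate per the config.

    When an output directory is given (from the config's output section
    or the argument), snapshots, manifests, the energy series and a
    fully resolved config echo are written there.
    """
    grid = cfg.build_grid()
    geom = cfg.build_geometry()
    layout = cfg.build_seeds()
    params = cfg.build_parameters()
    icfg = cfg.build_integrator()

    initial = seed_initial_state(grid, geom, layout, params)

    out = output_dir or (Path(cfg.output.directory)
                         if cfg.output.directory else None)
    callback = None
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(cfg.to_yaml())
        cfg_hash = cfg.config_hash()
        formats = list(cfg.output.snapshot_formats)

        def callback(step_idx: int, state: FieldState,
                     energy: EnergyBreakdown) -> None:
            stem = out / f"snapshot_{step_idx:07d}"
            manifest = {"step": step_idx, "time": state.time,
                        "time_seconds": state.time * cfg.parameters.time_scale,
                        "energy": energy.as_dict(),
                        "config_hash": cfg_hash,
                        "rng_seed": icfg.rng_seed}
            write_snapshot(state, stem, manifest=manifest, formats=formats)
            if "vti" in formats:
                write_vti(stem.with_suffix(".vti"),
                          {**{f"phi_{i}": state.phi[i]
                              for i in range(state.n_chromosomes)},
                           "psi1": state.psi1, "psi2": state.psi2,
                           "eta": state.eta},
                          spacing=grid.spacing)

    traj = run(initial, params, grid, icfg, snapshot_callback=callback)
    if out is not None:
        traj.energy_table().to_csv(out / "energy_series.csv", index=False)
        (out / "manifest.json").write_text(json.dumps({
            "n_steps": icfg.n_steps, "dt": icfg.dt,
            "scheme": icfg.scheme, "rng_seed": icfg.rng_seed,
            "config_hash": cfg.config_hash(),
            "snapshot_steps": traj.snapshot_steps,
            "wall_time_s": traj.wall_time_s}, indent=2))
    return traj
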