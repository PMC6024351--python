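"""File formats and run manifests.

CSV output is comma-separated, '.'-decimal, UTF-8 with a header row, written
deterministically so identical seeds give byte-identical files.  Voltage
frames go to legacy ASCII VTK structured-points files (one scalar field per
frame) readable by ParaView/VisIt.  Fibrosis masks round-trip through a
compressed ``.npz`` (bit-packed mask) with a human-readable sidecar header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import FibrosisField, TissueGeometry

__all__ = ["write_vtk_structured_points", "frames_to_vtk", "events_to_csv",
           "save_field", "load_field", "RunManifest", "write_outputs"]


def write_vtk_structured_points(path, values: np.ndarray, h: float,
                                name: str = "V", fill: float = -100.0) -> None:
    """Write one 3-D scalar field as a legacy ASCII VTK structured-points file.

    ``values`` has grid shape (nx, ny, nz); NaNs (non-conductive cells) are
    replaced by ``fill``.  VTK expects x-fastest point ordering, which is the
    transpose of our C-ordered grid.
    """
    v = np.asarray(values, dtype=float)
    nx, ny, nz = v.shape
    flat = np.where(np.isfinite(v), v, fill).transpose(2, 1, 0).ravel()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cardiomaze {name} field\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for start in range(0, flat.size, 9):
            fh.write(" ".join(f"{x:.4f}" for x in flat[start:start + 9]) + "\n")


def field_to_vtk(field_: FibrosisField, path) -> None:
    """Export a fibrosis field as a 0/1 (fibrotic/conductive) VTK scalar."""
    write_vtk_structured_points(path, field_.conductive.astype(float),
                                field_.geometry.h, name="conductive", fill=0.0)


def frames_to_vtk(record, directory, basename: str = "frame") -> list:
    """Write a simulation record's voltage frames as a VTK series + index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if record.frames is None:
        return []
    geo = record.geometry
    written = []
    for k, (t, row) in enumerate(zip(record.frame_times, record.frames)):
        grid = np.full(geo.n_cells, np.nan)
        grid[record.cell_index] = row
        path = directory / f"{basename}_{k:05d}.vtk"
        write_vtk_structured_points(path, grid.reshape(geo.shape), geo.h)
        written.append({"file": path.name, "time_ms": float(t)})
    index = directory / f"{basename}_index.json"
    index.write_text(json.dumps(written, indent=1))
    return written + [{"file": index.name, "time_ms": None}]


def events_to_csv(record, path) -> None:
    """Activation events as CSV (cell index, event time)."""
    frame = pd.DataFrame({
        "cell": record.cell_index[record.event_cells],
        "time_ms": record.event_times,
    })
    frame.to_csv(path, index=False)


def save_field(field_: FibrosisField, path) -> None:
    """Persist a fibrosis field: packed binary mask + text sidecar header."""
    path = Path(path)
    geo = field_.geometry
    np.savez_compressed(
        path.with_suffix(".npz"),
        conductive_bits=np.packbits(field_.conductive.ravel()),
        injured_bits=np.packbits(geo.injured_mask.ravel()),
        shape=np.array(geo.shape),
    )
    header = (f"cardiomaze fibrosis field\nnx={geo.nx} ny={geo.ny} nz={geo.nz}\n"
              f"h_cm={geo.h}\nphi={field_.phi}\nseed={field_.seed}\n"
              "indexing=0-based, x fastest (C order), axis-aligned\n")
    path.with_suffix(".txt").write_text(header)


def load_field(path) -> FibrosisField:
    path = Path(path)
    meta = {}
    for line in path.with_suffix(".txt").read_text().splitlines()[1:]:
        for tok in line.split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    data = np.load(path.with_suffix(".npz"))
    shape = tuple(int(x) for x in data["shape"])
    n = shape[0] * shape[1] * shape[2]
    conductive = np.unpackbits(data["conductive_bits"])[:n].astype(bool).reshape(shape)
    injured = np.unpackbits(data["injured_bits"])[:n].astype(bool).reshape(shape)
    geo = TissueGeometry(nx=shape[0], ny=shape[1], nz=shape[2],
                         h=float(meta["h_cm"]), injured_mask=injured)
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return FibrosisField(geometry=geo, conductive=conductive,
                         phi=float(meta["phi"]), seed=seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written beside every output set."""

    config: dict
    master_seed: int | None
    trial_seeds: list
    version: str
    wall_times_s: dict
    inventory: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def write_outputs(tables: dict, directory, config: dict | None = None,
                  master_seed: int | None = None, trial_seeds=None,
                  wall_times: dict | None = None) -> RunManifest:
    """Write a dict of DataFrames as CSVs plus a manifest with checksums.

    Idempotent: a re-run with the same inputs produces byte-identical CSVs.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        inventory = []
        for name, frame in tables.items():
            path = directory / f"{name}.csv"
            frame.to_csv(path, index=False, float_format="%.10g")
            inventory.append({"path": path.name, "sha256": _sha256(path)})
        manifest = RunManifest(
            config=config or {}, master_seed=master_seed,
            trial_seeds=[int(s) for s in (trial_seeds if trial_seeds is not None else [])],
            version=__version__, wall_times_s=wall_times or {},
            inventory=inventory)
        manifest.write(directory / "manifest.json")
        return manifest
    except OSError as exc:
        raise OSError(f"failed writing outputs under {directory}: {exc}") from exc
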