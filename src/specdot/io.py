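"""Plain-text readers and writers for every pipeline artifact.

Meshes are paired ``.node`` / ``.elem`` files (indices 1-based in files,
0-based in memory); measurement tables and characterization curves are CSV;
height calibrations are flat key=value text; fringe stacks are 16-bit TIFF
sequences with a sidecar manifest.  Every reader raises a ParseError naming
the file and line rather than silently truncating.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import SystemCharacterization
from .fem import MeasurementSet
from .meshing import TetMesh
from .profilometry import FringePatternSet, HeightCalibration, HeightMap

__all__ = [
    "ParseError",
    "save_mesh", "load_mesh",
    "save_measurements", "load_measurements",
    "save_height_calibration", "load_height_calibration",
    "save_height_map", "load_height_map",
    "save_fringe_stack", "load_fringe_stack",
    "save_recon_result", "export_mesh_vtk",
]


class ParseError(ValueError):
    """Malformed artifact file; message carries file and line."""


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def save_mesh(mesh: TetMesh, base) -> None:
    """Write ``<base>.node`` (x y z boundary-flag) and ``<base>.elem``
    (four 1-based node indices + region label)."""
    base = Path(base)
    flags = mesh.boundary_nodes().astype(int)
    with open(base.with_suffix(".node"), "w") as fh:
        for (x, y, z), b in zip(mesh.nodes, flags):
            fh.write(f"{x:.10g} {y:.10g} {z:.10g} {b}\n")
    with open(base.with_suffix(".elem"), "w") as fh:
        for el, r in zip(mesh.elements, mesh.regions):
            fh.write(f"{el[0]+1} {el[1]+1} {el[2]+1} {el[3]+1} {r}\n")


def load_mesh(base) -> TetMesh:
    base = Path(base)
    nodes, flags = [], []
    npath = base.with_suffix(".node")
    with open(npath) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{npath}:{ln}: expected 'x y z flag', got {len(parts)} fields")
            try:
                nodes.append([float(p) for p in parts[:3]])
                flags.append(int(parts[3]))
            except ValueError as exc:
                raise ParseError(f"{npath}:{ln}: {exc}") from None
    epath = base.with_suffix(".elem")
    elems, regions = [], []
    with open(epath) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5:
                raise ParseError(f"{epath}:{ln}: expected 4 indices + region, got {len(parts)} fields")
            try:
                idx = [int(p) - 1 for p in parts[:4]]
                reg = int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{epath}:{ln}: {exc}") from None
            if min(idx) < 0 or max(idx) >= len(nodes):
                raise ParseError(f"{epath}:{ln}: node index out of range")
            elems.append(idx)
            regions.append(reg)
    if not nodes or not elems:
        raise ParseError(f"{base}: empty mesh files")
    return TetMesh(np.array(nodes), np.array(elems), regions=np.array(regions))


def export_mesh_vtk(mesh: TetMesh, path) -> None:
    """Legacy-ASCII VTK export for visualization tools."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspecdot mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
        fh.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for el in mesh.elements:
            fh.write(f"4 {el[0]} {el[1]} {el[2]} {el[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["10"] * mesh.n_elements) + "\n")
        fh.write(f"CELL_DATA {mesh.n_elements}\nSCALARS region int 1\n")
        fh.write("LOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(r)) for r in mesh.regions) + "\n")


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def save_measurements(ms: MeasurementSet, path) -> None:
    df = ms.table.copy()
    df.insert(0, "role", ms.role)
    df.to_csv(path, index=False, float_format="%.17g")


def load_measurements(path) -> MeasurementSet:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    required = {"source", "detector", "wavelength", "amplitude"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df[sorted(required)].isna().any().any():
        bad = int(df[sorted(required)].isna().any(axis=1).idxmax()) + 2
        raise ParseError(f"{path}:{bad}: incomplete record")
    role = str(df["role"].iloc[0]) if "role" in df.columns else "measured"
    return MeasurementSet(df[["source", "detector", "wavelength", "amplitude"]],
                          role=role)


# ---------------------------------------------------------------------------
# height calibration / maps
# ---------------------------------------------------------------------------

def save_height_calibration(calib: HeightCalibration, path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(calib.C, start=1):
            fh.write(f"C{i}={c:.17g}\n")
        for i, d in enumerate(calib.D):
            fh.write(f"D{i}={d:.17g}\n")


def load_height_calibration(path) -> HeightCalibration:
    vals = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{ln}: expected key=value")
            k, v = line.split("=", 1)
            try:
                vals[k.strip()] = float(v)
            except ValueError:
                raise ParseError(f"{path}:{ln}: bad float {v!r}") from None
    try:
        C = [vals[f"C{i}"] for i in range(1, 6)]
        D = [vals[f"D{i}"] for i in range(6)]
    except KeyError as exc:
        raise ParseError(f"{path}: missing coefficient {exc}") from None
    return HeightCalibration(C=C, D=D)


def save_height_map(hm: HeightMap, path) -> None:
    np.savetxt(path, np.where(hm.mask, hm.values, np.nan),
               header=f"pitch_mm={hm.pitch}")


def load_height_map(path) -> HeightMap:
    pitch = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "pitch_mm=" in first:
            pitch = float(first.split("pitch_mm=")[1])
    values = np.loadtxt(path)
    return HeightMap(values, pitch=pitch)


# ---------------------------------------------------------------------------
# fringe stacks
# ---------------------------------------------------------------------------

def save_fringe_stack(patterns: FringePatternSet, directory) -> None:
    """16-bit TIFF per image plus a text manifest (frequency, shift, file)."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    peak = max(float(patterns.images.max()), 1e-12)
    scale = 60000.0 / peak
    with open(directory / "manifest.txt", "w") as fh:
        fh.write(f"# scale={scale:.17g}\n")
        fh.write("# frequency shift_rad filename\n")
        for i, f in enumerate(patterns.frequencies):
            for j, d in enumerate(patterns.phase_shifts):
                name = f"f{i:02d}_s{j:02d}.tif"
                img = np.clip(patterns.images[i, j] * scale, 0, 65535)
                tifffile.imwrite(directory / name, img.astype(np.uint16))
                fh.write(f"{f:.10g} {d:.17g} {name}\n")


def load_fringe_stack(directory) -> FringePatternSet:
    import tifffile

    directory = Path(directory)
    manifest = directory / "manifest.txt"
    scale = 1.0
    records = []
    with open(manifest) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("# scale="):
                scale = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{manifest}:{ln}: expected 'frequency shift file'")
            records.append((float(parts[0]), float(parts[1]), parts[2]))
    freqs = sorted({r[0] for r in records})
    shifts = sorted({r[1] for r in records})
    sample = tifffile.imread(directory / records[0][2])
    images = np.empty((len(freqs), len(shifts)) + sample.shape)
    for f, d, name in records:
        i, j = freqs.index(f), shifts.index(d)
        images[i, j] = tifffile.imread(directory / name).astype(float) / scale
    return FringePatternSet(images, tuple(freqs), tuple(shifts))


# ---------------------------------------------------------------------------
# characterization and reconstruction results
# ---------------------------------------------------------------------------

def save_characterization(char: SystemCharacterization, source_path,
                          response_path) -> None:
    char.to_csv(source_path, response_path)


def load_characterization(source_path, response_path) -> SystemCharacterization:
    return SystemCharacterization.from_csv(source_path, response_path)


def save_recon_result(result, directory) -> None:
    """Directory of delimited files: per-iteration trace, basis maps with
    extent metadata, and a JSON convergence log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_iter = len(result.projection_errors)
    pd.DataFrame({
        "iteration": np.arange(n_iter),
        "projection_error": result.projection_errors,
        "update_norm": [np.nan] + list(result.update_norms) + [np.nan] * (
            n_iter - 1 - len(result.update_norms)),
        "regularization": [np.nan] + list(result.reg_trace) + [np.nan] * (
            n_iter - 1 - len(result.reg_trace)),
    }).to_csv(directory / "iterations.csv", index=False)
    for name, values in result.concentrations_basis.items():
        np.savetxt(directory / f"concentration_{name}.txt", values,
                   header=f"basis dims={result.basis.dims} "
                          f"origin={tuple(result.basis.origin)} "
                          f"extent={tuple(result.basis.extent)} order={result.basis.order}")
    log = {
        "converged": bool(result.converged),
        "n_iterations": int(result.n_iterations),
        "parameters": list(result.parameters),
        "projection_errors": [float(e) for e in result.projection_errors],
        "basis": {"dims": list(result.basis.dims),
                  "origin": list(map(float, result.basis.origin)),
                  "extent": list(map(float, result.basis.extent)),
                  "order": result.basis.order},
    }
    with open(directory / "log.json", "w") as fh:
        json.dump(log, fh, indent=2)
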