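"""Readers and writers: cell/field snapshots (CSV, optional legacy VTK),
metrics series and YAML configuration files."""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import Grid
from .microenv import Field
from .params import Phase, SimulationConfig
from .population import CellPopulation

__all__ = [
    "write_snapshot",
    "read_population",
    "write_metrics",
    "save_config",
    "load_config",
]

CELL_COLUMNS = ["x", "y", "z", "phase", "V", "V_F", "V_NS", "V_CS"]


def population_frame(pop: CellPopulation) -> pd.DataFrame:
    """Cell table with columns x, y, z, phase (name), V, V_F, V_NS, V_CS."""
    return pd.DataFrame({
        "x": pop.position[:, 0], "y": pop.position[:, 1], "z": pop.position[:, 2],
        "phase": [Phase(p).name for p in pop.phase],
        "V": pop.V, "V_F": pop.V_F, "V_NS": pop.V_NS, "V_CS": pop.V_CS,
    })


def write_snapshot(pop: CellPopulation, field: Field, t_min: float, out_dir,
                   grid: Grid = None, write_vtk: bool = False) -> dict:
    """Write one snapshot; return the paths written.

    Cells go to ``cells_<tttttttt>.csv`` and the field to
    ``field_<tttttttt>.csv`` (i, j, k, rho), with the zero-padded time in
    whole minutes in the name.  With ``write_vtk`` the same data is also
    written as legacy ASCII VTK (PolyData points with phase and volume
    scalars; STRUCTURED_POINTS for the field).  Never mutates state.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"{int(round(t_min)):08d}"
    paths = {}

    cells_path = out_dir / f"cells_{tag}.csv"
    population_frame(pop).to_csv(cells_path, index=False, float_format="%.10g")
    paths["cells"] = cells_path

    nx, ny, nz = field.rho.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    field_path = out_dir / f"field_{tag}.csv"
    pd.DataFrame({"i": ii.ravel(), "j": jj.ravel(), "k": kk.ravel(),
                  "rho": field.rho.ravel()}).to_csv(field_path, index=False,
                                                    float_format="%.10g")
    paths["field"] = field_path

    if write_vtk:
        paths["cells_vtk"] = _write_cells_vtk(pop, out_dir / f"cells_{tag}.vtk")
        if grid is not None:
            paths["field_vtk"] = _write_field_vtk(field, grid,
                                                  out_dir / f"field_{tag}.vtk")
    return paths


def _write_cells_vtk(pop: CellPopulation, path: Path) -> Path:
    n = pop.n
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncellvox cells\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {n} double\n")
        for p in pop.position:
            f.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        f.write(f"POINT_DATA {n}\n")
        f.write("SCALARS phase int 1\nLOOKUP_TABLE default\n")
        for p in pop.phase:
            f.write(f"{int(p)}\n")
        f.write("SCALARS volume double 1\nLOOKUP_TABLE default\n")
        for v in pop.V:
            f.write(f"{v:.6g}\n")
    return path


def _write_field_vtk(field: Field, grid: Grid, path: Path) -> Path:
    nx, ny, nz = field.rho.shape
    o = grid.origin + 0.5 * grid.dx
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncellvox field\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {o[0]:.6g} {o[1]:.6g} {o[2]:.6g}\n")
        f.write(f"SPACING {grid.dx:.6g} {grid.dx:.6g} {grid.dx:.6g}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("SCALARS rho double 1\nLOOKUP_TABLE default\n")
        for v in field.rho.ravel(order="F"):
            f.write(f"{v:.10g}\n")
    return path


def read_population(path) -> CellPopulation:
    """Read a cell CSV back into a validated :class:`CellPopulation`.

    Raises ``ValueError`` naming the offending line for malformed rows,
    unknown phase labels or inconsistent component volumes.
    """
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    phase_codes = np.empty(len(df), dtype=np.int8)
    for row, label in enumerate(df["phase"]):
        try:
            phase_codes[row] = Phase[str(label)]
        except KeyError:
            raise ValueError(
                f"{path}, line {row + 2}: unknown phase label {label!r}") from None
    for col in ("x", "y", "z", "V", "V_F", "V_NS", "V_CS"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ValueError(f"{path}, line {bad[0] + 2}: non-numeric value in {col!r}")
        df[col] = vals

    pop = CellPopulation(df[["x", "y", "z"]].to_numpy(float), phase_codes,
                         df["V"].to_numpy(), df["V_F"].to_numpy(),
                         df["V_NS"].to_numpy(), df["V_CS"].to_numpy())
    comp = pop.V_F + pop.V_NS + pop.V_CS
    bad = np.flatnonzero(~np.isclose(pop.V, comp, rtol=1e-6, atol=1e-9))
    if bad.size:
        raise ValueError(f"{path}, line {bad[0] + 2}: V != V_F + V_NS + V_CS")
    return pop


def write_metrics(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def save_config(config: SimulationConfig, path) -> None:
    """Serialize a configuration to YAML (floats survive bit-for-bit)."""
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as f:
        return SimulationConfig.from_dict(yaml.safe_load(f))
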