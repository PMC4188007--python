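"""Reading and writing of geometry, spot tables and results.

Geometry lives in a YAML (or JSON) document with sections ``beam``,
``detector``, ``goniometer`` and ``scan``; spot tables are plain CSV
with columns ``x_px, y_px, z, var_x, var_y, var_z``.  Orientation
matrices are exported as plain text — nine numbers, row-major A (the
setting matrix, 1/Angstrom), followed by the cell parameters and a
space-group line — a format trivially convertible to XDS XPARM-style
inputs downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Beam, Crystal, Detector, Experiment, Goniometer, Scan, UnitCell

__all__ = [
    "load_geometry",
    "save_geometry",
    "read_spots",
    "write_spots",
    "write_assignments",
    "write_crystal",
    "read_crystal",
    "parse_cell",
]

SPOT_COLUMNS = ["x_px", "y_px", "z", "var_x", "var_y", "var_z"]


def geometry_to_dict(experiment: Experiment) -> dict:
    b, d, g, s = experiment.beam, experiment.detector, experiment.goniometer, experiment.scan
    return {
        "beam": {"wavelength": b.wavelength, "direction": [float(v) for v in b.direction]},
        "detector": {
            "fast_axis": [float(v) for v in d.fast_axis],
            "slow_axis": [float(v) for v in d.slow_axis],
            "origin": [float(v) for v in d.origin],
            "n_fast": d.n_fast,
            "n_slow": d.n_slow,
            "pixel_size": d.pixel_size,
        },
        "goniometer": {"axis": [float(v) for v in g.axis]},
        "scan": {"phi_start": s.phi_start, "delta_phi": s.delta_phi, "n_frames": s.n_frames},
    }


def geometry_from_dict(doc: dict) -> Experiment:
    return Experiment(
        beam=Beam(wavelength=doc["beam"]["wavelength"], direction=np.array(doc["beam"]["direction"])),
        detector=Detector(
            fast_axis=np.array(doc["detector"]["fast_axis"]),
            slow_axis=np.array(doc["detector"]["slow_axis"]),
            origin=np.array(doc["detector"]["origin"]),
            n_fast=int(doc["detector"]["n_fast"]),
            n_slow=int(doc["detector"]["n_slow"]),
            pixel_size=float(doc["detector"]["pixel_size"]),
        ),
        goniometer=Goniometer(axis=np.array(doc["goniometer"]["axis"])),
        scan=Scan(
            phi_start=float(doc["scan"]["phi_start"]),
            delta_phi=float(doc["scan"]["delta_phi"]),
            n_frames=int(doc["scan"]["n_frames"]),
        ),
    )


def load_geometry(path) -> Experiment:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return geometry_from_dict(doc)


def save_geometry(experiment: Experiment, path) -> None:
    path = Path(path)
    doc = geometry_to_dict(experiment)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_spots(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    return df


def write_spots(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, index=False)


def write_assignments(assignments: pd.DataFrame, path) -> None:
    out = assignments.copy()
    out["flags"] = np.where(out["outlier"], "outlier", "")
    cols = ["spot_id", "lattice_id", "h", "k", "l", "residual", "flags"]
    out[cols].to_csv(path, index=False)


def write_crystal(crystal: Crystal, path, space_group: str = "P1") -> None:
    """Plain-text export: row-major A, then cell, then space group."""
    lines = []
    for row in crystal.A:
        lines.append(" ".join(f"{v: .10e}" for v in row))
    lines.append(" ".join(f"{v:.6f}" for v in crystal.cell.parameters))
    lines.append(space_group)
    Path(path).write_text("\n".join(lines) + "\n")


def read_crystal(path) -> tuple[Crystal, str]:
    lines = Path(path).read_text().strip().splitlines()
    A = np.array([[float(v) for v in lines[i].split()] for i in range(3)])
    space_group = lines[4].strip()
    return Crystal.from_A(A), space_group


def parse_cell(text: str) -> UnitCell:
    """Parse 'a,b,c,alpha,beta,gamma' (angles optional, default 90)."""
    parts = [float(p) for p in text.replace(",", " ").split()]
    if len(parts) == 3:
        parts += [90.0, 90.0, 90.0]
    if len(parts) != 6:
        raise ValueError("cell must have 3 or 6 numbers: a,b,c[,alpha,beta,gamma]")
    return UnitCell(*parts)
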