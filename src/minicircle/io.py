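"""Curve, bead-model and shape serialisation.

Formats
-------
* CSV — three columns ``x,y,z`` in Å, one row per control point, closure
  implicit.
* JSON — ``{"control_points": [...], "length_bp": ..., "dLk": ...,
  "labels": {...}}``.
* PDB/XYZ — pseudo-atom export of bead models or centerlines (one atom per
  bead, occupancy column = bead diameter) for visualisation tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import ClosedCurve

__all__ = [
    "curve_to_csv", "curve_from_csv", "curve_to_json", "curve_from_json",
    "shape_to_dict", "export_pdb", "export_xyz",
]


def curve_to_csv(curve: ClosedCurve, path: str | Path) -> None:
    df = pd.DataFrame(curve.control_points, columns=["x", "y", "z"])
    df.to_csv(path, index=False)


def curve_from_csv(path: str | Path) -> ClosedCurve:
    df = pd.read_csv(path)
    return ClosedCurve(df[["x", "y", "z"]].to_numpy())


def curve_to_json(curve: ClosedCurve, path: str | Path | None = None,
                  length_bp: int | None = None, dLk: float | None = None,
                  labels: dict | None = None) -> dict:
    record = {
        "control_points": curve.control_points.tolist(),
        "length_bp": length_bp,
        "dLk": dLk,
        "labels": labels or {},
    }
    if path is not None:
        Path(path).write_text(json.dumps(record, indent=1))
    return record


def curve_from_json(source: str | Path | dict) -> tuple[ClosedCurve, dict]:
    """Returns (curve, metadata) where metadata carries length_bp/dLk/labels."""
    if isinstance(source, dict):
        record = source
    else:
        record = json.loads(Path(source).read_text())
    curve = ClosedCurve(np.asarray(record["control_points"], dtype=float))
    meta = {k: record.get(k) for k in ("length_bp", "dLk", "labels")}
    return curve, meta


def shape_to_dict(shape) -> dict:
    """JSON-ready summary of an EquilibriumShape (curve + energies + Wr)."""
    topo = shape.topology
    return {
        "control_points": shape.curve.control_points.tolist(),
        "contour_length": shape.curve.arclength(),
        "energy_total_kT": shape.energy_total,
        "energy_bend_kT": shape.energy_bend,
        "energy_twist_kT": shape.energy_twist,
        "penalty_residual_kT": shape.penalty_residual,
        "writhe": shape.writhe,
        "n_contacts": shape.n_contacts,
        "contact_type": shape.contact_type,
        "converged": shape.converged,
        "seed": shape.seed,
        "topology": None if topo is None else {
            "length_bp": topo.length_bp, "h": topo.helical_repeat_h,
            "Lk": topo.Lk, "Lk0": topo.Lk0, "dLk": topo.dLk,
            "sigma": topo.sigma, "Tw": topo.Tw, "Wr": topo.Wr,
        },
    }


def export_pdb(points: np.ndarray, path: str | Path,
               bead_diameter: float = 20.0) -> None:
    """Write pseudo-atom PDB (HETATM per bead, occupancy = bead diameter)."""
    pts = np.asarray(points, dtype=float)
    lines = []
    for i, (x, y, z) in enumerate(pts, start=1):
        serial = i % 100000
        lines.append(
            f"HETATM{serial:5d}  C   BEA A{(i % 10000):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{bead_diameter:6.2f}{0.0:6.2f}"
            f"          C")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def export_xyz(points: np.ndarray, path: str | Path,
               comment: str = "minicircle centerline (Å)") -> None:
    pts = np.asarray(points, dtype=float)
    lines = [str(len(pts)), comment]
    lines += [f"C {x:.4f} {y:.4f} {z:.4f}" for x, y, z in pts]
    Path(path).write_text("\n".join(lines) + "\n")
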