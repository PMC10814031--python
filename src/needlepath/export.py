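"""Exports: face-map images, VTK polylines, CSV summaries, distance fields."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .anatomy import LabeledVolume, write_volume
from .constraints import FaceMapSet
from .geometry import DistanceField
from .grid import FACES, face_grid_shape
from .planner import PlanResult
from .verify import RunReport


def _to_uint16(grid: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    out = np.zeros(grid.shape, dtype=np.uint16)
    ok = ~np.isnan(grid)
    if vmax > vmin:
        out[ok] = np.round(65535.0 * np.clip((grid[ok] - vmin) / (vmax - vmin), 0.0, 1.0)).astype(np.uint16)
    else:
        out[ok] = 65535
    return out


def save_face_maps(fm: FaceMapSet, outdir: str | Path) -> None:
    """Write 16-bit grayscale PNGs per face per map plus a JSON sidecar.

    The feasibility map follows the binary convention: blocked cells 0, open
    cells full intensity. Normalized soft maps span [0, 65535]; cells owned by
    a higher-priority face (deduplicated edges) are rendered as 0.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layers: dict[str, tuple[np.ndarray, float, float]] = {
        "feasible": (fm.feasible.astype(float), 0.0, 1.0),
    }
    for name in ("R", "L", "A"):
        vals = getattr(fm, name)
        if vals is not None:
            layers[name] = (vals, 0.0, 1.0)
    for name, (vals, vmin, vmax) in layers.items():
        for face in FACES:
            grid = fm.face_grid(face, vals, fill=np.nan)
            img = Image.fromarray(_to_uint16(grid.T, vmin, vmax))  # v rows, u columns
            img.save(outdir / f"facemap_{name}_{face.replace('+', 'p').replace('-', 'm')}.png")
    sidecar = {
        "faces": {f: list(face_grid_shape(f, fm.cells.shape)) for f in FACES},
        "cells": len(fm),
        "target_C_mm": [float(x) for x in fm.C],
        "extrema": {k: (None if v != v else float(v)) for k, v in fm.extrema.items()},
        "counts": fm.counts,
        "value_scale": "uint16 0..65535 maps to normalized score 0..1",
    }
    with open(outdir / "facemaps.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def save_vtk_polylines(result: PlanResult, path: str | Path) -> None:
    """Planned trajectories as legacy ASCII VTK polylines (I -> C per path)."""
    lines = [
        "# vtk DataFile Version 3.0",
        "planned needle trajectories",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {2 * len(result.paths)} float",
    ]
    for p in result.paths:
        lines.append(" ".join(f"{x:.3f}" for x in p.I))
        lines.append(" ".join(f"{x:.3f}" for x in p.C))
    lines.append(f"LINES {len(result.paths)} {3 * len(result.paths)}")
    for i in range(len(result.paths)):
        lines.append(f"2 {2 * i} {2 * i + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_report_csv(report: RunReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "rank",
                "cell_id",
                "qualified",
                "h1_fail",
                "h2_fail",
                "h3_fail",
                "h4_fail",
                "d_mm",
                "l_mm",
                "alpha_deg",
                "excellent",
            ]
        )
        for v in report.verdicts:
            writer.writerow(
                [v.rank, v.cell_id, v.qualified, v.h1, v.h2, v.h3, v.h4, f"{v.d:.2f}", f"{v.l:.2f}", f"{v.alpha:.2f}", v.excellent]
            )


def save_distance_field(field: DistanceField, path: str | Path) -> None:
    """Distance field as a (rounded) integer NIfTI for slice-wise inspection."""
    vol = LabeledVolume(
        labels=np.round(field.values).astype(np.int32),
        spacing=field.spacing,
        origin=field.origin,
    )
    write_volume(vol, path)
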