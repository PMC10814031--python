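"""Pipeline orchestration: face maps -> H1-H4 -> S1-S3 -> Pareto -> top-k."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .anatomy import AnatomyScene, PlanConfig, tumor_centroid
from .constraints import (
    CandidatePath,
    FaceMapSet,
    PlannerContext,
    build_face_maps,
    evaluate_hard,
    evaluate_soft,
)
from .grid import FACES
from .optimize import select_top_k

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_FEASIBLE = "no_feasible_path"


@dataclass
class PlanResult:
    """Ranked trajectories with full constraint provenance."""

    status: str
    paths: list[CandidatePath]
    C: np.ndarray
    counts: dict
    extrema: dict
    fallback_used: bool
    config: PlanConfig
    scene_checksum: str
    dominant_failure: str | None = None
    version: str = field(default=__version__)

    def to_dict(self) -> dict:
        def vec(v):
            return None if v is None or np.any(np.isnan(v)) else [float(x) for x in v]

        return {
            "version": self.version,
            "status": self.status,
            "scene_checksum": self.scene_checksum,
            "target_C_mm": [float(x) for x in self.C],
            "counts": self.counts,
            "extrema": {k: (None if v != v else float(v)) for k, v in self.extrema.items()},
            "pareto_fallback_used": bool(self.fallback_used),
            "dominant_failure": self.dominant_failure,
            "config": json.loads(self.config.model_dump_json()),
            "paths": [
                {
                    "rank": p.rank,
                    "cell_id": int(p.cell_id),
                    "face": p.face,
                    "uv": [int(p.uv[0]), int(p.uv[1])],
                    "I_mm": vec(p.I),
                    "E_mm": vec(p.E),
                    "P_mm": vec(p.P),
                    "C_mm": vec(p.C),
                    "d_mm": float(p.d),
                    "l_mm": float(p.l),
                    "alpha_deg": float(p.alpha),
                    "R": float(p.R),
                    "L": float(p.L),
                    "A": float(p.A),
                    "G": float(p.G),
                }
                for p in self.paths
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"


def plan(scene: AnatomyScene, config: PlanConfig) -> tuple[PlanResult, FaceMapSet]:
    """Run the full planning pipeline on one scene.

    Returns the ranked plan and the fully populated face-map set (feasibility,
    flags, raw values and normalized grayscale scores per candidate cell).
    """
    C = tumor_centroid(scene)
    fm = build_face_maps(scene, C)
    logger.info("candidate cells: %d", len(fm))
    ctx = PlannerContext(scene, config)
    evaluate_hard(ctx, fm)
    logger.info("constraint counts: %s", fm.counts)
    checksum = scene.checksum()

    if fm.counts["feasible"] == 0:
        fails = {k: fm.counts[k] for k in ("h1_fail", "h2_fail", "h3_fail", "h4_fail")}
        dominant = max(fails, key=fails.get)
        return (
            PlanResult(
                status=STATUS_NO_FEASIBLE,
                paths=[],
                C=C,
                counts=fm.counts,
                extrema={},
                fallback_used=False,
                config=config,
                scene_checksum=checksum,
                dominant_failure=dominant,
            ),
            fm,
        )

    evaluate_soft(ctx, fm)
    feas_idx = np.flatnonzero(fm.feasible)
    values = np.stack([fm.R[feas_idx], fm.L[feas_idx], fm.A[feas_idx]], axis=1)
    sel, g, fallback, front_size = select_top_k(
        feas_idx, values, config.weights, config.top_k, config.aggregate
    )
    fm.counts["pareto_front"] = front_size

    paths: list[CandidatePath] = []
    for rank, (pos, gi) in enumerate(zip(sel, g), start=1):
        cid = int(feas_idx[pos])
        paths.append(
            CandidatePath(
                cell_id=cid,
                face=FACES[fm.cells.face_id[cid]],
                uv=(int(fm.cells.uv[cid, 0]), int(fm.cells.uv[cid, 1])),
                I=fm.points[cid],
                C=C,
                E=fm.E[cid],
                P=fm.P[cid],
                d=float(fm.d[cid]),
                l=float(fm.l[cid]),
                alpha=float(fm.alpha[cid]),
                R=float(fm.R[cid]),
                L=float(fm.L[cid]),
                A=float(fm.A[cid]),
                G=float(gi),
                rank=rank,
            )
        )

    result = PlanResult(
        status=STATUS_OK,
        paths=paths,
        C=C,
        counts=fm.counts,
        extrema=fm.extrema,
        fallback_used=fallback,
        config=config,
        scene_checksum=checksum,
    )
    return result, fm
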