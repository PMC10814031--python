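"""Independent re-verification of planned trajectories.

Every returned path is re-traced against H1-H4 with the scalar reference
checker (built on :mod:`needlepath.geometry`), which shares no tracing code
with the planner's vectorized classification. On top of the hard-constraint
re-check, three excellence standards are evaluated per path: distance to risk
structures > 10 mm, percutaneous length < 100 mm, entry angle > 70°.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .anatomy import AnatomyScene, PlanConfig
from .constraints import ScalarChecker
from .errors import VerificationError

EXCELLENT_DISTANCE_MM = 10.0
EXCELLENT_LENGTH_MM = 100.0
EXCELLENT_ANGLE_DEG = 70.0


@dataclass
class PathVerdict:
    rank: int
    cell_id: int
    h1: bool
    h2: bool
    h3: bool
    h4: bool
    l: float
    alpha: float
    d: float
    qualified: bool
    excellent_distance: bool
    excellent_length: bool
    excellent_angle: bool

    @property
    def excellent(self) -> bool:
        return self.excellent_distance and self.excellent_length and self.excellent_angle


@dataclass
class RunReport:
    """Pass/excellence summary over the returned paths."""

    verdicts: list[PathVerdict]
    pass_rate: float
    excellent_rate: float
    excellent_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_paths": len(self.verdicts),
            "pass_rate_percent": self.pass_rate,
            "excellent_rate_percent": self.excellent_rate,
            "excellent_counts": self.excellent_counts,
            "paths": [
                {
                    "rank": v.rank,
                    "cell_id": v.cell_id,
                    "h1_fail": v.h1,
                    "h2_fail": v.h2,
                    "h3_fail": v.h3,
                    "h4_fail": v.h4,
                    "l_mm": v.l,
                    "alpha_deg": v.alpha,
                    "d_mm": v.d,
                    "qualified": v.qualified,
                    "excellent": v.excellent,
                    "excellent_distance": v.excellent_distance,
                    "excellent_length": v.excellent_length,
                    "excellent_angle": v.excellent_angle,
                }
                for v in self.verdicts
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"


def _verify_one(
    checker: ScalarChecker,
    risk_field: geometry.DistanceField | None,
    I,
    C,
    rank: int,
    cell_id: int,
) -> PathVerdict:
    res = checker.check_all(np.asarray(I, float), np.asarray(C, float))
    # Independent S1 distance for the excellence standard.
    d = math.inf
    if risk_field is not None:
        d = math.nan
        entry = checker.skin_entry(np.asarray(I, float), np.asarray(C, float))
        if entry is not None:
            E, _ = entry
            seg = geometry.Segment(E, C)
            d = geometry.min_along_segment(risk_field, seg, checker.step)
    return PathVerdict(
        rank=rank,
        cell_id=cell_id,
        h1=res["h1"],
        h2=res["h2"],
        h3=res["h3"],
        h4=res["h4"],
        l=res["l"],
        alpha=res["alpha"],
        d=d,
        qualified=res["pass"],
        excellent_distance=bool(d > EXCELLENT_DISTANCE_MM),
        excellent_length=bool(res["l"] < EXCELLENT_LENGTH_MM),
        excellent_angle=bool(res["alpha"] > EXCELLENT_ANGLE_DEG),
    )


def verify_plan(scene: AnatomyScene, plan_dict: dict, config: PlanConfig | None = None) -> RunReport:
    """Re-verify a serialized plan against the scene it was computed on."""
    if plan_dict.get("scene_checksum") not in (None, scene.checksum()):
        raise VerificationError("plan was computed on a different scene (checksum mismatch)")
    if config is None:
        config = PlanConfig(**plan_dict["config"])
    checker = ScalarChecker(scene, config)
    risk_field = (
        geometry.distance_transform_mask(scene.risk_mask(), scene.spacing, scene.origin)
        if scene.risk_mask().any()
        else None
    )
    C = np.asarray(plan_dict["target_C_mm"], float)
    verdicts = [
        _verify_one(checker, risk_field, np.asarray(p["I_mm"], float), C, p["rank"], p["cell_id"])
        for p in plan_dict["paths"]
    ]
    n = len(verdicts)
    pass_rate = 100.0 * sum(v.qualified for v in verdicts) / n if n else math.nan
    exc_rate = 100.0 * sum(v.excellent for v in verdicts) / n if n else math.nan
    counts = {
        "distance_gt_10mm": sum(v.excellent_distance for v in verdicts),
        "length_lt_100mm": sum(v.excellent_length for v in verdicts),
        "angle_gt_70deg": sum(v.excellent_angle for v in verdicts),
        "all_three": sum(v.excellent for v in verdicts),
    }
    return RunReport(verdicts=verdicts, pass_rate=pass_rate, excellent_rate=exc_rate, excellent_counts=counts)
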