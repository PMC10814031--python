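"""Face maps, hard-constraint filtering (H1-H4), and grayscale soft maps.

Every boundary voxel of the CT bounding box defines one candidate trajectory:
the segment from its center I to the tumor centroid C. Enumerating boundary
voxels directly realizes the corrected cube mapping (one sight line per
surface cell, bijective by construction) without any camera bookkeeping.

Hard constraints:

* H1 — the segment must not cross any risk structure (bones, bronchi,
  vessels, heart, mediastinum, the non-target lung). Occlusion is defined as
  the segment reaching the 0.5 level of the trilinearly interpolated risk
  occupancy, the sub-voxel analogue of colliding with a marching-cubes
  isosurface of the risk labels.
* H2 — the percutaneous length l = |E - C| (E = skin entry) must be strictly
  less than the needle length.
* H3 — the pleural entry angle α at the lung entry point P must be strictly
  greater than the clinical threshold (default 20°).
* H4 — the expected ablation zone (tumor + ablation margin), grown by the
  required insertion depth, must not poke through the lung parenchyma along
  the path.

Soft constraints (grayscale maps, normalized over the feasible set):

* S1 — minimum distance d from the percutaneous portion of the path to the
  risk structures (distance transform + per-ray minimum projection),
  R = (d - d_min) / (d_max - d_min);
* S2 — percutaneous length l, L = 1 - (l - l_min) / (l_max - l_min);
* S3 — entry angle α, A = (α - α_min) / (α_max - α_min) so that larger entry
  angles score higher, matching the stated clinical goal.

The vectorized engine here is the planner's classification path; the scalar
``check_h*`` functions below are the independent reference implementations
built on :mod:`needlepath.geometry`, used by the verifier and the tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import geometry
from .anatomy import AnatomyScene, PlanConfig
from .errors import EmptyStructureError, GeometryError
from .grid import BoundaryCells, enumerate_boundary_cells

logger = logging.getLogger(__name__)

_OCC_LEVEL = 0.5
_BISECT_ITERS = 6  # refines a ray_step bracket well below 0.1 mm at <=2 mm steps


# ---------------------------------------------------------------------------
# Strict boundary predicates (shared semantics, single definition)
# ---------------------------------------------------------------------------
def h2_passes(length_mm: float | np.ndarray, needle_length_mm: float):
    """H2: percutaneous length strictly less than the needle length."""
    return np.asarray(length_mm) < needle_length_mm


def h3_passes(alpha_deg: float | np.ndarray, angle_threshold_deg: float):
    """H3: entry angle strictly greater than the threshold."""
    return np.asarray(alpha_deg) > angle_threshold_deg


# ---------------------------------------------------------------------------
# Face map container
# ---------------------------------------------------------------------------
@dataclass
class FaceMapSet:
    """Per-cell candidate data over the six bounding-box faces.

    Hard-constraint flags are True where the constraint FAILS. ``feasible`` is
    the OR-integration of the four layers (plus geometric degeneracies such as
    rays that never enter the body or the target lobe, which are grouped with
    H1/H2 as each constraint's definition dictates).
    """

    cells: BoundaryCells
    points: np.ndarray  # (N, 3) insertion points I, world mm
    C: np.ndarray  # target point

    h1: np.ndarray | None = None
    h2: np.ndarray | None = None
    h3: np.ndarray | None = None
    h4: np.ndarray | None = None
    h1_occluded: np.ndarray | None = None  # pure occlusion layer (oracle-comparable)
    no_lung_entry: np.ndarray | None = None
    no_body_entry: np.ndarray | None = None
    feasible: np.ndarray | None = None

    t_entry: np.ndarray | None = None  # skin-entry parameter along I->C
    E: np.ndarray | None = None
    P: np.ndarray | None = None
    l: np.ndarray | None = None
    alpha: np.ndarray | None = None
    d: np.ndarray | None = None
    R: np.ndarray | None = None
    L: np.ndarray | None = None
    A: np.ndarray | None = None
    extrema: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    def face_grid(self, face: str, values: np.ndarray, fill=np.nan) -> np.ndarray:
        return self.cells.face_grid(face, values, fill)


def build_face_maps(scene: AnatomyScene, C: np.ndarray) -> FaceMapSet:
    """Bind every boundary voxel to a candidate segment I -> C."""
    C = np.asarray(C, dtype=float)
    lo = scene.origin
    hi = scene.origin + (np.asarray(scene.shape) - 1) * scene.spacing
    if not np.all((C > lo) & (C < hi)):
        raise GeometryError("target point must lie strictly inside the bounding box")
    cells = enumerate_boundary_cells(scene.shape)
    points = scene.volume.index_to_world(cells.ijk)
    return FaceMapSet(cells=cells, points=points, C=C)


# ---------------------------------------------------------------------------
# Planner context: precomputed fields
# ---------------------------------------------------------------------------
class PlannerContext:
    """Volumetric fields shared by the vectorized constraint layers."""

    def __init__(self, scene: AnatomyScene, config: PlanConfig):
        self.scene = scene
        self.config = config
        self.spacing = scene.spacing
        self.origin = scene.origin
        self.step = config.resolved_ray_step(scene.spacing)

        labels = scene.labels
        self.risk_occ = geometry.occupancy_from_mask(scene.risk_mask())
        self.inbody_occ = geometry.occupancy_from_mask(labels > 0)
        self.lobe_occ = geometry.occupancy_from_mask(scene.role_mask("lung_target_lobe"))

        sampling = tuple(float(s) for s in self.spacing)
        if scene.risk_mask().any():
            self.risk_edt = ndimage.distance_transform_edt(
                ~scene.risk_mask(), sampling=sampling
            ).astype(np.float32)
        else:
            self.risk_edt = None  # no risk structures: S1 degenerate

        # Outward-normal field of the target lobe (smoothed-mask gradient).
        self.lung_grad = geometry.smoothed_gradient(
            scene.role_mask("lung_target_lobe"), self.spacing, geometry.NORMAL_SIGMA_VOX
        )

        self.h4_occ = self._build_h4_mask()
        self._tumor_field: np.ndarray | None = None

    def _build_h4_mask(self) -> np.ndarray | None:
        cfg = self.config
        tumor = self.scene.role_mask("tumor")
        if not tumor.any():
            raise EmptyStructureError("tumor mask is empty")
        sampling = tuple(float(s) for s in self.spacing)
        dist = ndimage.distance_transform_edt(~tumor, sampling=sampling)
        grown = dist <= (cfg.ablation_margin_mm + cfg.depth_margin_mm)
        parenchyma = self.scene.role_mask("lung_target_lobe", "tumor") | (
            self.scene.role_mask("lung_other") if "lung_other" in self.scene.roles else False
        )
        # vessels/bronchi embedded in the lung are anatomically surrounded by
        # parenchyma and already guarded by H1; H4 targets the pleural wall
        shell = grown & ~parenchyma & ~self.scene.risk_mask()
        if not shell.any():
            return None
        return geometry.occupancy_from_mask(shell)

    def tumor_distance_field(self, C: np.ndarray) -> np.ndarray:
        """Distance (mm) to the voxel containing the tumor centroid (for the S2 MIP route)."""
        if self._tumor_field is None:
            idx = np.rint((np.asarray(C, float) - self.origin) / self.spacing).astype(int)
            idx = np.clip(idx, 0, np.asarray(self.scene.shape) - 1)
            mask = np.zeros(self.scene.shape, dtype=bool)
            mask[tuple(idx)] = True
            self._tumor_field = ndimage.distance_transform_edt(
                ~mask, sampling=tuple(float(s) for s in self.spacing)
            ).astype(np.float32)
        return self._tumor_field

    def interp(self, fieldvals: np.ndarray, vox_coords: np.ndarray) -> np.ndarray:
        """Trilinear sampling at continuous voxel coordinates (…, 3)."""
        flat = vox_coords.reshape(-1, 3).T
        out = ndimage.map_coordinates(fieldvals, flat, order=1, mode="nearest")
        return out.reshape(vox_coords.shape[:-1])


# ---------------------------------------------------------------------------
# Vectorized engine
# ---------------------------------------------------------------------------
def _bisect_occ(ctx: PlannerContext, I, D, t_lo, t_hi, occ, iters=_BISECT_ITERS):
    """Vectorized bisection of the 0.5-occupancy crossing on [t_lo, t_hi]."""
    for _ in range(iters):
        mid = 0.5 * (t_lo + t_hi)
        pts = I + mid[:, None] * D
        vals = ctx.interp(occ, (pts - ctx.origin) / ctx.spacing)
        inside = vals >= _OCC_LEVEL
        t_hi = np.where(inside, mid, t_hi)
        t_lo = np.where(inside, t_lo, mid)
    return t_hi


def _first_level_index(vals: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Per-row index of the first sample >= 0.5 among valid samples (-1: none)."""
    inside = vals >= _OCC_LEVEL
    if valid is not None:
        inside &= valid
    any_row = inside.any(axis=1)
    idx = np.where(any_row, inside.argmax(axis=1), -1)
    return idx


def evaluate_hard(ctx: PlannerContext, fm: FaceMapSet) -> None:
    """Fill the four hard-constraint layers and the path geometry columns."""
    cfg = ctx.config
    n = len(fm)
    h1 = np.zeros(n, dtype=bool)
    h2 = np.zeros(n, dtype=bool)
    h3 = np.zeros(n, dtype=bool)
    h4 = np.zeros(n, dtype=bool)
    no_lung = np.zeros(n, dtype=bool)
    no_body = np.zeros(n, dtype=bool)
    t_entry = np.full(n, np.nan)
    E = np.full((n, 3), np.nan)
    P = np.full((n, 3), np.nan)
    l_arr = np.full(n, np.nan)
    alpha = np.full(n, np.nan)

    C = fm.C
    chunk = 4096
    for lo in range(0, n, chunk):
        sl = slice(lo, min(lo + chunk, n))
        I = fm.points[sl]
        D = C[None, :] - I
        seg_len = np.linalg.norm(D, axis=1)
        n_steps = max(1, int(math.ceil(seg_len.max() / ctx.step)))
        ts = np.linspace(0.0, 1.0, n_steps + 1)
        pts = I[:, None, :] + ts[None, :, None] * D[:, None, :]
        vox = (pts - ctx.origin) / ctx.spacing

        occ_risk = ctx.interp(ctx.risk_occ, vox)
        h1[sl] = (occ_risk >= _OCC_LEVEL).any(axis=1)

        occ_body = ctx.interp(ctx.inbody_occ, vox)
        k_body = _first_level_index(occ_body)
        nb = k_body <= 0  # never enters the body, or starts inside it
        no_body[sl] = nb
        ok = ~nb
        if ok.any():
            kk = k_body[ok]
            t_lo = ts[kk - 1]
            t_hi = ts[kk]
            tE = _bisect_occ(ctx, I[ok], D[ok], t_lo, t_hi, ctx.inbody_occ)
            full_tE = np.full(len(I), np.nan)
            full_tE[ok] = tE
            t_entry[sl] = full_tE
            Echunk = np.full((len(I), 3), np.nan)
            Echunk[ok] = I[ok] + tE[:, None] * D[ok]
            E[sl] = Echunk
            lchunk = np.full(len(I), np.nan)
            lchunk[ok] = (1.0 - tE) * seg_len[ok]
            l_arr[sl] = lchunk
            h2[sl] = np.where(ok, ~h2_passes(np.where(ok, lchunk, 0.0), cfg.needle_length_mm), False)

        # Lung entry after the skin entry.
        occ_lobe = ctx.interp(ctx.lobe_occ, vox)
        tE_col = t_entry[sl]
        valid = ts[None, :] > np.where(np.isnan(tE_col), np.inf, tE_col)[:, None]
        k_lobe = _first_level_index(occ_lobe, valid)
        nl = (k_lobe < 0) & ~nb
        no_lung[sl] = nl
        okl = (k_lobe > 0) & ~nb
        if okl.any():
            kk = k_lobe[okl]
            tP = _bisect_occ(ctx, I[okl], D[okl], ts[kk - 1], ts[kk], ctx.lobe_occ)
            Pp = I[okl] + tP[:, None] * D[okl]
            Pchunk = np.full((len(I), 3), np.nan)
            Pchunk[okl] = Pp
            P[sl] = Pchunk
            voxP = (Pp - ctx.origin) / ctx.spacing
            g = np.stack([ctx.interp(gc, voxP) for gc in ctx.lung_grad], axis=1)
            gn = np.linalg.norm(g, axis=1)
            dirn = D[okl] / seg_len[okl][:, None]
            cosang = np.abs(np.einsum("ij,ij->i", dirn, -g)) / np.maximum(gn, 1e-12)
            ang = 90.0 - np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
            achunk = np.full(len(I), np.nan)
            achunk[okl] = ang
            alpha[sl] = achunk
            h3chunk = np.zeros(len(I), dtype=bool)
            h3chunk[okl] = ~h3_passes(ang, cfg.angle_threshold_deg) | (gn < 1e-9)
            h3[sl] = h3chunk

        if ctx.h4_occ is not None:
            occ_h4 = ctx.interp(ctx.h4_occ, vox)
            h4[sl] = (occ_h4 >= _OCC_LEVEL).any(axis=1)

    fm.h1_occluded = h1
    fm.h1 = h1 | no_lung  # a path that never reaches the lung is H1-style infeasible
    fm.h2 = h2 | no_body
    fm.h3 = h3
    fm.h4 = h4
    fm.no_lung_entry = no_lung
    fm.no_body_entry = no_body
    fm.t_entry = t_entry
    fm.E = E
    fm.P = P
    fm.l = l_arr
    fm.alpha = alpha
    integrate_hard(fm)


def integrate_hard(fm: FaceMapSet) -> np.ndarray:
    """OR-integrate the four non-feasible layers into the binary feasibility map."""
    for layer in ("h1", "h2", "h3", "h4"):
        if getattr(fm, layer) is None:
            raise GeometryError(f"hard-constraint layer {layer} not computed")
    fm.feasible = ~(fm.h1 | fm.h2 | fm.h3 | fm.h4)
    n = len(fm)
    fm.counts = {
        "cells": n,
        "h1_fail": int(fm.h1.sum()),
        "h2_fail": int(fm.h2.sum()),
        "h3_fail": int(fm.h3.sum()),
        "h4_fail": int(fm.h4.sum()),
        "feasible": int(fm.feasible.sum()),
    }
    return fm.feasible


# ---------------------------------------------------------------------------
# Soft constraint maps (Eqs. of the grayscale constraint maps)
# ---------------------------------------------------------------------------
def normalize_s1(d: np.ndarray, feasible: np.ndarray) -> tuple[np.ndarray, dict]:
    """R = (d - d_min) / (d_max - d_min) over feasible cells; higher is safer."""
    return _normalize(d, feasible, invert=False, names=("d_min", "d_max"))


def normalize_s2(l: np.ndarray, feasible: np.ndarray) -> tuple[np.ndarray, dict]:
    """L = 1 - (l - l_min) / (l_max - l_min); shorter paths score higher."""
    return _normalize(l, feasible, invert=True, names=("l_min", "l_max"))


def normalize_s3(
    alpha: np.ndarray, feasible: np.ndarray, printed_form: bool = False
) -> tuple[np.ndarray, dict]:
    """A = (α - α_min) / (α_max - α_min); steeper entry scores higher.

    ``printed_form=True`` selects the inverted variant (1 - …), which rewards
    shallow entry angles and contradicts both the clinical preference and the
    >70° excellence criterion; it is retained only for sensitivity analysis.
    """
    return _normalize(alpha, feasible, invert=printed_form, names=("alpha_min", "alpha_max"))


def _normalize(raw, feasible, invert: bool, names: tuple[str, str]):
    raw = np.asarray(raw, dtype=float)
    score = np.full(raw.shape, np.nan)
    if not feasible.any():
        return score, {names[0]: math.nan, names[1]: math.nan}
    vals = raw[feasible]
    vmin, vmax = float(np.min(vals)), float(np.max(vals))
    if vmax - vmin < 1e-12:
        score[feasible] = 1.0  # degenerate range: all candidates equally good
    else:
        s = (vals - vmin) / (vmax - vmin)
        score[feasible] = 1.0 - s if invert else s
    return score, {names[0]: vmin, names[1]: vmax}


def evaluate_soft(ctx: PlannerContext, fm: FaceMapSet) -> None:
    """Compute raw d/l/α grids and their normalized scores over the feasible set."""
    cfg = ctx.config
    n = len(fm)
    d = np.full(n, np.nan)
    C = fm.C
    if ctx.risk_edt is not None:
        chunk = 4096
        for lo in range(0, n, chunk):
            sl = slice(lo, min(lo + chunk, n))
            I = fm.points[sl]
            D = C[None, :] - I
            seg_len = np.linalg.norm(D, axis=1)
            n_steps = max(1, int(math.ceil(seg_len.max() / ctx.step)))
            ts = np.linspace(0.0, 1.0, n_steps + 1)
            pts = I[:, None, :] + ts[None, :, None] * D[:, None, :]
            vox = (pts - ctx.origin) / ctx.spacing
            vals = ctx.interp(ctx.risk_edt, vox)
            if not cfg.s1_full_ray:
                tE = fm.t_entry[sl]
                mask = ts[None, :] >= np.where(np.isnan(tE), np.inf, tE)[:, None]
                vals = np.where(mask, vals, np.inf)
                # include the refined entry point itself
                okE = ~np.isnan(tE)
                if okE.any():
                    Ept = fm.E[sl][okE]
                    atE = ctx.interp(ctx.risk_edt, (Ept - ctx.origin) / ctx.spacing)
                    dmin = vals[okE].min(axis=1)
                    sub = np.minimum(dmin, atE)
                    block = np.full(len(I), np.nan)
                    block[okE] = sub
                    d[sl] = block
                    continue
            d[sl] = vals.min(axis=1)
        d[np.isinf(d)] = np.nan
    else:
        d[fm.feasible] = np.inf  # no risk structures anywhere

    fm.d = d
    R, ext1 = normalize_s1(d, fm.feasible) if ctx.risk_edt is not None else (
        np.where(fm.feasible, 1.0, np.nan),
        {"d_min": math.nan, "d_max": math.nan},
    )
    L, ext2 = normalize_s2(fm.l, fm.feasible)
    A, ext3 = normalize_s3(fm.alpha, fm.feasible, printed_form=cfg.s3_printed_form)
    fm.R, fm.L, fm.A = R, L, A
    fm.extrema = {**ext1, **ext2, **ext3}


def s2_mip_lengths(ctx: PlannerContext, fm: FaceMapSet, cell_indices: np.ndarray) -> np.ndarray:
    """Percutaneous length via the distance-field + maximum-projection route.

    A distance field is grown from the tumor centroid, clipped to the interior
    of the body, and the maximum along each sight line is taken — the ray
    analogue of rendering a MIP of the clipped field. Cross-checks |E - C|.
    """
    fieldvals = ctx.tumor_distance_field(fm.C)
    out = np.full(len(cell_indices), np.nan)
    C = fm.C
    chunk = 4096
    for lo in range(0, len(cell_indices), chunk):
        sel = cell_indices[lo : lo + chunk]
        I = fm.points[sel]
        D = C[None, :] - I
        seg_len = np.linalg.norm(D, axis=1)
        n_steps = max(1, int(math.ceil(seg_len.max() / ctx.step)))
        ts = np.linspace(0.0, 1.0, n_steps + 1)
        pts = I[:, None, :] + ts[None, :, None] * D[:, None, :]
        vox = (pts - ctx.origin) / ctx.spacing
        vals = ctx.interp(fieldvals, vox)
        inside = ctx.interp(ctx.inbody_occ, vox) >= _OCC_LEVEL
        vals = np.where(inside, vals, 0.0)  # outside the chest: lowest gray value
        best = vals.max(axis=1)
        tE = fm.t_entry[sel]
        okE = ~np.isnan(tE)
        if okE.any():
            Ept = fm.E[sel][okE]
            atE = ctx.interp(fieldvals, (Ept - ctx.origin) / ctx.spacing)
            best[okE] = np.maximum(best[okE], atE)
        out[lo : lo + chunk] = best
    return out


# ---------------------------------------------------------------------------
# Scalar reference checks (independent of the vectorized engine)
# ---------------------------------------------------------------------------
@dataclass
class CandidatePath:
    """One candidate trajectory with raw values, scores, and provenance."""

    cell_id: int
    face: str
    uv: tuple[int, int]
    I: np.ndarray
    C: np.ndarray
    E: np.ndarray | None = None
    P: np.ndarray | None = None
    d: float = math.nan
    l: float = math.nan
    alpha: float = math.nan
    R: float = math.nan
    L: float = math.nan
    A: float = math.nan
    G: float = math.nan
    rank: int = -1


class ScalarChecker:
    """Reference hard-constraint checks built on the geometry module.

    Shares no tracing code with :func:`evaluate_hard`; used by the independent
    verifier and to spot-check the vectorized engine cell by cell.
    """

    def __init__(self, scene: AnatomyScene, config: PlanConfig):
        self.scene = scene
        self.config = config
        self.step = config.resolved_ray_step(scene.spacing)
        self.risk_occ = geometry.occupancy_from_mask(scene.risk_mask())
        self.inbody_occ = geometry.occupancy_from_mask(scene.labels > 0)
        self.lobe_occ = geometry.occupancy_from_mask(scene.role_mask("lung_target_lobe"))
        self._h4_field = None
        tumor = scene.role_mask("tumor")
        if tumor.any():
            self._h4_field = geometry.distance_transform_mask(
                tumor, scene.spacing, scene.origin
            )
        self._parenchyma = scene.role_mask("lung_target_lobe", "tumor")
        if "lung_other" in scene.roles:
            self._parenchyma = self._parenchyma | scene.role_mask("lung_other")

    def _occ_field(self, occ: np.ndarray) -> geometry.DistanceField:
        return geometry.DistanceField(values=occ, spacing=self.scene.spacing, origin=self.scene.origin)

    def check_h1(self, I: np.ndarray, C: np.ndarray) -> bool:
        """True when the segment I->C is occluded by a risk structure."""
        seg = geometry.Segment(I, C)
        return geometry.max_along_segment(self._occ_field(self.risk_occ), seg, self.step) >= _OCC_LEVEL

    def skin_entry(self, I: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, float] | None:
        seg = geometry.Segment(I, C)
        t = geometry.occupancy_crossing(
            self.inbody_occ, self.scene.spacing, self.scene.origin, seg, self.step
        )
        if t is None or t <= 0.0:
            return None
        E = seg.point(t)
        return E, t

    def check_h2(self, I: np.ndarray, C: np.ndarray) -> tuple[bool, float]:
        """(fails, l). Raises GeometryError when the ray never enters the body."""
        entry = self.skin_entry(I, C)
        if entry is None:
            raise GeometryError("no skin crossing on the segment (insertion point inside the body?)")
        E, _ = entry
        l = float(np.linalg.norm(E - np.asarray(C, float)))
        return not bool(h2_passes(l, self.config.needle_length_mm)), l

    def lung_entry(self, I: np.ndarray, C: np.ndarray) -> np.ndarray | None:
        entry = self.skin_entry(I, C)
        if entry is None:
            return None
        _, tE = entry
        seg = geometry.Segment(I, C)
        t = geometry.occupancy_crossing(
            self.lobe_occ, self.scene.spacing, self.scene.origin, seg, self.step, t_min=tE
        )
        return None if t is None else seg.point(t)

    def check_h3(self, I: np.ndarray, C: np.ndarray) -> tuple[bool, float]:
        """(fails, α). A path that never enters the target lobe fails H1-style."""
        P = self.lung_entry(I, C)
        if P is None:
            return True, math.nan
        normal = geometry.surface_normal(self.scene, "lung_target_lobe", P)
        seg = geometry.Segment(I, C)
        alpha = geometry.path_surface_angle(seg.direction, normal)
        return not bool(h3_passes(alpha, self.config.angle_threshold_deg)), alpha

    def h4_mask(self) -> np.ndarray | None:
        if self._h4_field is None:
            return None
        grown = self._h4_field.values <= (
            self.config.ablation_margin_mm + self.config.depth_margin_mm
        )
        shell = grown & ~self._parenchyma & ~self.scene.risk_mask()
        return shell if shell.any() else None  # callers smooth before level queries

    def check_h4(self, I: np.ndarray, C: np.ndarray) -> bool:
        shell = self.h4_mask()
        if shell is None:
            return False
        seg = geometry.Segment(I, C)
        occ = self._occ_field(geometry.occupancy_from_mask(shell))
        return geometry.max_along_segment(occ, seg, self.step) >= _OCC_LEVEL

    def check_all(self, I: np.ndarray, C: np.ndarray) -> dict:
        """Re-verify one path against H1-H4; returns flags and raw values."""
        res: dict = {}
        res["h1"] = self.check_h1(I, C)
        try:
            h2, l = self.check_h2(I, C)
        except GeometryError:
            h2, l = True, math.nan
        res["h2"], res["l"] = h2, l
        h3, alpha = self.check_h3(I, C)
        if math.isnan(alpha):
            res["h1"] = True  # never reaches the lung
            h3 = False
        res["h3"], res["alpha"] = h3, alpha
        res["h4"] = self.check_h4(I, C)
        res["pass"] = not (res["h1"] or res["h2"] or res["h3"] or res["h4"])
        return res
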