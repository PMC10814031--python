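"""Deterministic synthetic thorax phantoms with an exact geometric oracle.

The phantom emulates the structure set a segmented clinical thorax CT
provides: skin shell, torso soft tissue, two lungs, heart, mediastinum,
trachea with main bronchi, intrapulmonary vessels, rib cage, and a spherical
tumor inside one lung. All structures are analytic primitives (ellipsoids,
finite cylinders, torus arcs), so candidate-trajectory occlusion can be
answered in closed form, independent of any voxelization — the
:func:`shadow_oracle` below. This makes the whole planning pipeline testable
without clinical data.

The default specification is mirror-symmetric about the sagittal (x) plane
except for the tumor; the optional jitter is applied symmetrically so the
symmetry is preserved bit-exactly for any seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from .anatomy import AnatomyScene, LabeledVolume
from .errors import ConfigurationError
from .grid import enumerate_boundary_cells

# Fixed label assignment of the generator.
LABELS = {
    "skin": 1,
    "body": 2,
    "lung_right": 3,
    "lung_left": 4,
    "heart": 5,
    "bronchi": 6,
    "vessels": 7,
    "bone": 8,
    "mediastinum": 9,
    "tumor": 10,
}


# ---------------------------------------------------------------------------
# Analytic primitives
# ---------------------------------------------------------------------------
class Primitive:
    """Closed analytic solid supporting membership and segment-hit queries."""

    def contains(self, pts: np.ndarray) -> np.ndarray:  # (N, 3) -> (N,)
        raise NotImplementedError

    def segment_hits(self, starts: np.ndarray, end: np.ndarray) -> np.ndarray:
        """True per start point when the segment start->end meets the solid."""
        raise NotImplementedError

    def rasterize(self, X: np.ndarray, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Membership of voxel centers given broadcastable coordinate grids."""
        raise NotImplementedError


def _interval_overlap(lo1, hi1, lo2, hi2):
    return np.maximum(lo1, lo2) <= np.minimum(hi1, hi2)


@dataclass(frozen=True)
class Ellipsoid(Primitive):
    center: tuple[float, float, float]
    half_axes: tuple[float, float, float]

    def _q(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, float)
        a = np.asarray(self.half_axes, float)
        u = (np.asarray(pts, float) - c) / a
        return np.einsum("...i,...i->...", u, u)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self._q(pts) <= 1.0

    def rasterize(self, X, Y, Z):
        c, a = self.center, self.half_axes
        return ((X - c[0]) / a[0]) ** 2 + ((Y - c[1]) / a[1]) ** 2 + ((Z - c[2]) / a[2]) ** 2 <= 1.0

    def segment_hits(self, starts: np.ndarray, end: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, float)
        a = np.asarray(self.half_axes, float)
        u = (np.asarray(starts, float) - c) / a  # (N, 3)
        v = (np.asarray(end, float) - c) / a - u
        a2 = np.einsum("ij,ij->i", v, v)
        b = 2.0 * np.einsum("ij,ij->i", u, v)
        c0 = np.einsum("ij,ij->i", u, u) - 1.0
        hit = np.zeros(len(u), dtype=bool)
        deg = a2 < 1e-15
        hit[deg] = c0[deg] <= 0.0
        nd = ~deg
        disc = b[nd] ** 2 - 4.0 * a2[nd] * c0[nd]
        ok = disc >= 0.0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t1 = (-b[nd] - sq) / (2.0 * a2[nd])
        t2 = (-b[nd] + sq) / (2.0 * a2[nd])
        hit[nd] = ok & _interval_overlap(t1, t2, 0.0, 1.0)
        return hit


@dataclass(frozen=True)
class Cylinder(Primitive):
    """Finite circular cylinder with flat caps, arbitrary axis p0 -> p1."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def _frame(self):
        p0 = np.asarray(self.p0, float)
        w = np.asarray(self.p1, float) - p0
        length = float(np.linalg.norm(w))
        return p0, w / length, length

    def contains(self, pts: np.ndarray) -> np.ndarray:
        p0, axis, length = self._frame()
        rel = np.asarray(pts, float) - p0
        s = rel @ axis
        radial = rel - np.multiply.outer(s, axis)
        return (s >= 0) & (s <= length) & (np.einsum("...i,...i->...", radial, radial) <= self.radius**2)

    def rasterize(self, X, Y, Z):
        p0, axis, length = self._frame()
        rx, ry, rz = X - p0[0], Y - p0[1], Z - p0[2]
        s = rx * axis[0] + ry * axis[1] + rz * axis[2]
        qx, qy, qz = rx - s * axis[0], ry - s * axis[1], rz - s * axis[2]
        return (s >= 0) & (s <= length) & (qx * qx + qy * qy + qz * qz <= self.radius**2)

    def segment_hits(self, starts: np.ndarray, end: np.ndarray) -> np.ndarray:
        p0, axis, length = self._frame()
        I = np.asarray(starts, float)
        D = np.asarray(end, float) - I  # (N, 3)
        rel = I - p0
        s0 = rel @ axis
        sD = D @ axis
        q0 = rel - np.multiply.outer(s0, axis)
        qD = D - np.multiply.outer(sD, axis)
        a2 = np.einsum("ij,ij->i", qD, qD)
        b = 2.0 * np.einsum("ij,ij->i", q0, qD)
        c0 = np.einsum("ij,ij->i", q0, q0) - self.radius**2

        n = len(I)
        tr_lo = np.full(n, np.inf)
        tr_hi = np.full(n, -np.inf)
        deg_r = a2 < 1e-15
        inside_r = deg_r & (c0 <= 0.0)
        tr_lo[inside_r], tr_hi[inside_r] = -np.inf, np.inf
        nd = ~deg_r
        disc = b[nd] ** 2 - 4.0 * a2[nd] * c0[nd]
        ok = disc >= 0.0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        lo = (-b[nd] - sq) / (2.0 * a2[nd])
        hi = (-b[nd] + sq) / (2.0 * a2[nd])
        tr_lo[nd] = np.where(ok, lo, np.inf)
        tr_hi[nd] = np.where(ok, hi, -np.inf)

        ta_lo = np.full(n, np.inf)
        ta_hi = np.full(n, -np.inf)
        deg_a = np.abs(sD) < 1e-15
        inside_a = deg_a & (s0 >= 0) & (s0 <= length)
        ta_lo[inside_a], ta_hi[inside_a] = -np.inf, np.inf
        nda = ~deg_a
        t_at_0 = (0.0 - s0[nda]) / sD[nda]
        t_at_L = (length - s0[nda]) / sD[nda]
        ta_lo[nda] = np.minimum(t_at_0, t_at_L)
        ta_hi[nda] = np.maximum(t_at_0, t_at_L)

        lo_all = np.maximum.reduce([tr_lo, ta_lo, np.zeros(n)])
        hi_all = np.minimum.reduce([tr_hi, ta_hi, np.ones(n)])
        return lo_all <= hi_all


@dataclass(frozen=True)
class TorusArcZ(Primitive):
    """Arc of a (possibly elliptic) torus whose plane is z = center_z.

    The guiding curve is the ellipse with semi-axes ``major_axes`` = (a, b) in
    the plane; with a == b this is the ordinary circular torus. The tube is
    the set where ``(sqrt(a*b) * (g - 1))^2 + (z - cz)^2 <= r^2`` with
    ``g = sqrt((dx/a)^2 + (dy/b)^2)`` — for a = b exactly the torus implicit,
    for moderate ellipticity a tube whose width varies by the axis ratio.
    The arc covers azimuths from ``phi0`` counterclockwise over ``span``
    radians. Segment intersection is answered by dense sampling restricted to
    the slab |z - center_z| <= tube_radius, which bounds the region where a
    hit is possible; within the slab the samples are spaced finely relative
    to the tube radius.
    """

    center: tuple[float, float, float]
    major_axes: tuple[float, float]
    tube_radius: float
    phi0: float
    span: float

    def _membership(self, x, y, z):
        cx, cy, cz = self.center
        a, b = self.major_axes
        dx, dy = x - cx, y - cy
        g = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
        s = math.sqrt(a * b)
        tube = (s * (g - 1.0)) ** 2 + (z - cz) ** 2 <= self.tube_radius**2
        ang = np.mod(np.arctan2(dy, dx) - self.phi0, 2.0 * math.pi)
        return tube & (ang <= self.span)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        p = np.asarray(pts, float)
        return self._membership(p[..., 0], p[..., 1], p[..., 2])

    def rasterize(self, X, Y, Z):
        return self._membership(X, Y, Z)

    def segment_hits(self, starts: np.ndarray, end: np.ndarray, n_samples: int = 256) -> np.ndarray:
        I = np.asarray(starts, float)
        C = np.asarray(end, float)
        D = C - I
        cz, r = self.center[2], self.tube_radius
        n = len(I)
        lo = np.zeros(n)
        hi = np.ones(n)
        dz = D[:, 2]
        deg = np.abs(dz) < 1e-15
        t_a = np.where(deg, 0.0, (cz - r - I[:, 2]) / np.where(deg, 1.0, dz))
        t_b = np.where(deg, 1.0, (cz + r - I[:, 2]) / np.where(deg, 1.0, dz))
        slab_lo = np.minimum(t_a, t_b)
        slab_hi = np.maximum(t_a, t_b)
        # Degenerate rays parallel to the rib plane keep the whole [0, 1] range
        # unless they miss the slab entirely.
        miss_deg = deg & (np.abs(I[:, 2] - cz) > r)
        lo = np.where(deg, 0.0, np.maximum(lo, slab_lo))
        hi = np.where(deg, 1.0, np.minimum(hi, slab_hi))
        active = (lo <= hi) & ~miss_deg
        hits = np.zeros(n, dtype=bool)
        if not active.any():
            return hits
        ts = np.linspace(0.0, 1.0, n_samples)
        la, ha = lo[active], hi[active]
        tt = la[:, None] + ts[None, :] * (ha - la)[:, None]
        pts = I[active, None, :] + tt[..., None] * D[active, None, :]
        mem = self._membership(pts[..., 0], pts[..., 1], pts[..., 2])
        hits[active] = mem.any(axis=1)
        return hits


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------
class PhantomSpec(BaseModel):
    """Parameters of the synthetic thorax scene.

    Distances are in mm, in world coordinates (``origin`` at the center of
    voxel (0,0,0)). Lung/heart/mediastinum positions are offsets from the
    volume center so the same anatomy scales to coarser test grids; the tumor
    center is absolute. ``jitter_mm`` perturbs rib levels and vessel endpoints
    (mirror-symmetrically) with a deterministic generator seeded by ``seed``.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    body_half_axes: tuple[float, float, float] = (105.0, 95.0, 125.0)
    skin_thickness_mm: float = Field(default=4.0, gt=0)

    lung_half_axes: tuple[float, float, float] = (32.0, 52.0, 85.0)
    lung_center_offset: tuple[float, float, float] = (52.0, -5.0, 5.0)

    include_heart: bool = True
    heart_center_offset: tuple[float, float, float] = (0.0, 23.0, -17.0)
    heart_half_axes: tuple[float, float, float] = (30.0, 26.0, 33.0)

    include_mediastinum: bool = True
    mediastinum_radius: float = 13.0
    mediastinum_y_offset: float = -5.0
    mediastinum_z_range: tuple[float, float] = (-47.0, 73.0)

    include_bronchi: bool = True
    trachea_radius: float = 9.0
    trachea_y_offset: float = -9.0
    trachea_z_range: tuple[float, float] = (25.0, 113.0)
    bronchus_radius: float = 6.0
    hilum_offset: tuple[float, float, float] = (45.0, -5.0, 13.0)

    rib_count: int = Field(default=12, ge=0)
    rib_arc_span_deg: float = 70.0
    rib_tube_radius_mm: float = 3.5
    # ribs follow the inner-skin cross-section scaled by this factor, so the
    # cage tracks the tapering torso instead of poking through it
    rib_fit_factor: float = 0.93
    rib_z_extent: tuple[float, float] = (-57.0, 58.0)

    # Right-lung vessel segments as offsets from the right hilum; mirrored to
    # the left lung. Entries: (dx, dy, dz of tip, radius).
    vessels: tuple[tuple[float, float, float, float], ...] = (
        (28.0, -20.0, 35.0, 4.0),
        (33.0, 20.0, -25.0, 4.0),
        (18.0, 30.0, 20.0, 3.5),
    )

    tumor_center: tuple[float, float, float] = (186.0, 100.0, 120.0)
    tumor_radius: float = Field(default=15.0, gt=0)

    jitter_mm: float = Field(default=1.0, ge=0)
    seed: int = 0

    @property
    def volume_center(self) -> np.ndarray:
        return np.asarray(self.origin, float) + (np.asarray(self.shape, float) - 1.0) * np.asarray(self.spacing, float) / 2.0


@dataclass
class ResolvedPhantom:
    """Concrete primitive set after jitter, in rasterization order."""

    spec: PhantomSpec
    body: Ellipsoid
    body_inner: Ellipsoid  # body minus skin shell
    lungs: dict[str, Ellipsoid]  # keys "right" (+x), "left" (-x)
    target_side: str
    tumor: Ellipsoid
    # (primitive, label) in rasterization order after body/lungs.
    organs: list[tuple[Primitive, int]]

    def risk_primitives(self, risk_labels: frozenset[int]) -> list[Primitive]:
        prims: list[Primitive] = [p for p, lab in self.organs if lab in risk_labels]
        other = "left" if self.target_side == "right" else "right"
        if LABELS["lung_" + other] in risk_labels:
            prims.append(self.lungs[other])
        return prims


def _mirror_x(point, cx: float):
    return (2.0 * cx - point[0], point[1], point[2])


def resolve_phantom(spec: PhantomSpec) -> ResolvedPhantom:
    """Apply jitter and lay out the concrete primitive list."""
    center = spec.volume_center
    cx = float(center[0])
    rng = np.random.default_rng(spec.seed)

    def jit(n: int) -> np.ndarray:
        if spec.jitter_mm <= 0:
            return np.zeros(n)
        return rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=n)

    body = Ellipsoid(tuple(center), spec.body_half_axes)
    inner_axes = tuple(max(a - spec.skin_thickness_mm, 1.0) for a in spec.body_half_axes)
    body_inner = Ellipsoid(tuple(center), inner_axes)

    off = np.asarray(spec.lung_center_offset, float)
    lung_r = Ellipsoid(tuple(center + off * np.array([1.0, 1.0, 1.0])), spec.lung_half_axes)
    lung_l = Ellipsoid(tuple(center + off * np.array([-1.0, 1.0, 1.0])), spec.lung_half_axes)
    lungs = {"right": lung_r, "left": lung_l}

    tumor = Ellipsoid(spec.tumor_center, (spec.tumor_radius,) * 3)
    target_side = "right" if spec.tumor_center[0] >= cx else "left"
    target_lung = lungs[target_side]
    tc = np.asarray(spec.tumor_center, float)
    lc = np.asarray(target_lung.center, float)
    shrunk = np.asarray(target_lung.half_axes, float) - spec.tumor_radius
    if np.any(shrunk <= 0) or float(np.sum(((tc - lc) / shrunk) ** 2)) > 1.0:
        raise ConfigurationError("tumor sphere is not fully inside a lung ellipsoid")

    organs: list[tuple[Primitive, int]] = []

    if spec.include_mediastinum:
        y = center[1] + spec.mediastinum_y_offset
        z0, z1 = (center[2] + v for v in spec.mediastinum_z_range)
        organs.append(
            (Cylinder((cx, y, z0), (cx, y, z1), spec.mediastinum_radius), LABELS["mediastinum"])
        )

    if spec.include_heart:
        organs.append(
            (Ellipsoid(tuple(center + np.asarray(spec.heart_center_offset, float)), spec.heart_half_axes), LABELS["heart"])
        )

    hilum_r = center + np.asarray(spec.hilum_offset, float)
    if spec.include_bronchi:
        ty = center[1] + spec.trachea_y_offset
        tz0, tz1 = (center[2] + v for v in spec.trachea_z_range)
        organs.append((Cylinder((cx, ty, tz0), (cx, ty, tz1), spec.trachea_radius), LABELS["bronchi"]))
        carina = (cx, ty, tz0)
        organs.append((Cylinder(carina, tuple(hilum_r), spec.bronchus_radius), LABELS["bronchi"]))
        organs.append((Cylinder(carina, _mirror_x(tuple(hilum_r), cx), spec.bronchus_radius), LABELS["bronchi"]))

    for dx, dy, dz, r in spec.vessels:
        delta = np.array([dx, dy, dz]) + jit(3)
        tip_r = tuple(hilum_r + delta)
        organs.append((Cylinder(tuple(hilum_r), tip_r, r), LABELS["vessels"]))
        organs.append((Cylinder(_mirror_x(tuple(hilum_r), cx), _mirror_x(tip_r, cx), r), LABELS["vessels"]))

    n_levels = spec.rib_count // 2
    if n_levels > 0:
        z_lo, z_hi = (center[2] + v for v in spec.rib_z_extent)
        levels = np.linspace(z_lo, z_hi, n_levels) if n_levels > 1 else np.array([(z_lo + z_hi) / 2.0])
        levels = levels + jit(n_levels)
        span = math.radians(spec.rib_arc_span_deg)
        c_body = spec.body_half_axes[2]
        for z in levels:
            taper = math.sqrt(max(1.0 - ((float(z) - float(center[2])) / c_body) ** 2, 0.01))
            a_k = spec.rib_fit_factor * inner_axes[0] * taper
            b_k = spec.rib_fit_factor * inner_axes[1] * taper
            for phi_mid in (0.0, math.pi):  # right (+x) and left (-x) arcs
                organs.append(
                    (
                        TorusArcZ(
                            (cx, float(center[1]), float(z)),
                            (a_k, b_k),
                            spec.rib_tube_radius_mm,
                            phi_mid - span / 2.0,
                            span,
                        ),
                        LABELS["bone"],
                    )
                )

    return ResolvedPhantom(
        spec=spec,
        body=body,
        body_inner=body_inner,
        lungs=lungs,
        target_side=target_side,
        tumor=tumor,
        organs=organs,
    )


def generate_phantom(spec: PhantomSpec) -> AnatomyScene:
    """Rasterize the phantom into a labeled scene with roles pre-bound.

    Later structures overwrite earlier ones in the fixed order
    body < lungs < mediastinum < heart < bronchi < vessels < ribs < tumor,
    with the skin shell carved out of the body ellipsoid first. Output is
    bit-exactly reproducible for identical spec + seed.
    """
    resolved = resolve_phantom(spec)
    shape = spec.shape
    spacing = np.asarray(spec.spacing, float)
    origin = np.asarray(spec.origin, float)
    X = (origin[0] + spacing[0] * np.arange(shape[0], dtype=np.float64))[:, None, None]
    Y = (origin[1] + spacing[1] * np.arange(shape[1], dtype=np.float64))[None, :, None]
    Z = (origin[2] + spacing[2] * np.arange(shape[2], dtype=np.float64))[None, None, :]

    labels = np.zeros(shape, dtype=np.int16)
    body_mask = resolved.body.rasterize(X, Y, Z)
    labels[body_mask] = LABELS["body"]
    labels[body_mask & ~resolved.body_inner.rasterize(X, Y, Z)] = LABELS["skin"]
    other_side = "left" if resolved.target_side == "right" else "right"
    for side in (other_side, resolved.target_side):  # target lobe wins overlaps
        labels[resolved.lungs[side].rasterize(X, Y, Z)] = LABELS["lung_" + side]
    for prim, lab in resolved.organs:
        labels[prim.rasterize(X, Y, Z)] = lab
    labels[resolved.tumor.rasterize(X, Y, Z)] = LABELS["tumor"]

    target_lab = LABELS["lung_" + resolved.target_side]
    other_lab = LABELS["lung_left" if resolved.target_side == "right" else "lung_right"]
    roles: dict[str, tuple[int, ...]] = {
        "skin": (LABELS["skin"],),
        "lung_target_lobe": (target_lab,),
        "tumor": (LABELS["tumor"],),
    }
    optional = {
        "lung_other": other_lab,
        "heart": LABELS["heart"],
        "bronchi": LABELS["bronchi"],
        "vessels": LABELS["vessels"],
        "bone": LABELS["bone"],
        "mediastinum": LABELS["mediastinum"],
    }
    present = set(np.unique(labels).tolist())
    for role, lab in optional.items():
        if lab in present:
            roles[role] = (lab,)

    volume = LabeledVolume(labels=labels, spacing=spacing, origin=origin)
    return AnatomyScene(volume=volume, roles=roles)


def shadow_oracle(
    spec: PhantomSpec | ResolvedPhantom,
    C: np.ndarray,
    cell_points: np.ndarray | None = None,
    chunk: int = 8192,
    risk_labels: frozenset[int] | None = None,
) -> np.ndarray:
    """Analytic occlusion of bounding-box cells as seen from the target C.

    For each candidate insertion point I (by default: every boundary voxel
    center), returns True when the segment I->C intersects any analytic risk
    primitive of the phantom — computed from the primitives themselves,
    independent of voxelization. This is the ground truth for the voxelized
    H1 classification.
    """
    resolved = spec if isinstance(spec, ResolvedPhantom) else resolve_phantom(spec)
    sp = resolved.spec
    if cell_points is None:
        cells = enumerate_boundary_cells(sp.shape)
        cell_points = np.asarray(sp.origin, float) + cells.ijk * np.asarray(sp.spacing, float)
    cell_points = np.asarray(cell_points, float)
    C = np.asarray(C, float)

    if risk_labels is None:
        risk_labels = frozenset(
            LABELS[r] for r in ("bone", "bronchi", "vessels", "heart", "mediastinum")
        ) | {LABELS["lung_left"], LABELS["lung_right"]}
    prims = resolved.risk_primitives(risk_labels)

    occluded = np.zeros(len(cell_points), dtype=bool)
    for lo in range(0, len(cell_points), chunk):
        sl = slice(lo, lo + chunk)
        block = cell_points[sl]
        hit = np.zeros(len(block), dtype=bool)
        for prim in prims:
            todo = ~hit
            if not todo.any():
                break
            hit[todo] |= prim.segment_hits(block[todo], C)
        occluded[sl] = hit
    return occluded
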