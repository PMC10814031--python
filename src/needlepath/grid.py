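"""Enumeration of the bounding-box surface.

Every boundary voxel of the volume is a candidate insertion point. Each is
assigned to exactly one of the six box faces; voxels on edges and corners are
deduplicated by the fixed priority x-, x+, y-, y+, z-, z+, so the number of
candidate trajectories equals ``W*H*D - (W-2)*(H-2)*(D-2)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical face order (also the edge/corner ownership priority).
FACES = ("x-", "x+", "y-", "y+", "z-", "z+")

#: For each face: (fixed axis, fixed index is 0-side?, (u axis, v axis)).
_FACE_DEF = {
    "x-": (0, True, (1, 2)),
    "x+": (0, False, (1, 2)),
    "y-": (1, True, (0, 2)),
    "y+": (1, False, (0, 2)),
    "z-": (2, True, (0, 1)),
    "z+": (2, False, (0, 1)),
}


def boundary_cell_count(shape: tuple[int, int, int]) -> int:
    w, h, d = shape
    return w * h * d - max(w - 2, 0) * max(h - 2, 0) * max(d - 2, 0)


def face_grid_shape(face: str, shape: tuple[int, int, int]) -> tuple[int, int]:
    ax_u, ax_v = _FACE_DEF[face][2]
    return shape[ax_u], shape[ax_v]


@dataclass(frozen=True)
class BoundaryCells:
    """Flat, deterministic enumeration of all boundary voxels.

    Arrays are aligned; ``cell_id`` is the position in this canonical order
    (faces in :data:`FACES` order, row-major (u, v) within each face).
    ``owned`` per (face, u, v) is implicit: u/v ranges already exclude cells
    owned by a higher-priority face.
    """

    shape: tuple[int, int, int]
    face_id: np.ndarray  # (N,) uint8, index into FACES
    uv: np.ndarray  # (N, 2) int32, position in the face grid
    ijk: np.ndarray  # (N, 3) int32, voxel index

    def __len__(self) -> int:
        return self.face_id.shape[0]

    def face_grid(self, face: str, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter per-cell values onto the 2D grid of one face.

        Grid positions owned by a higher-priority face keep ``fill``.
        """
        fi = FACES.index(face)
        grid = np.full(face_grid_shape(face, self.shape), fill, dtype=np.asarray(values).dtype if fill is not np.nan else float)
        sel = self.face_id == fi
        grid[self.uv[sel, 0], self.uv[sel, 1]] = values[sel]
        return grid


def enumerate_boundary_cells(shape: tuple[int, int, int]) -> BoundaryCells:
    w, h, d = (int(s) for s in shape)
    faces_ijk: list[np.ndarray] = []
    faces_uv: list[np.ndarray] = []
    face_ids: list[np.ndarray] = []

    def add(face: str, ijk: np.ndarray) -> None:
        ax_u, ax_v = _FACE_DEF[face][2]
        uv = np.stack([ijk[:, ax_u], ijk[:, ax_v]], axis=1)
        faces_ijk.append(ijk)
        faces_uv.append(uv)
        face_ids.append(np.full(len(ijk), FACES.index(face), dtype=np.uint8))

    def mesh(ii, jj, kk) -> np.ndarray:
        a, b, c = np.meshgrid(ii, jj, kk, indexing="ij")
        return np.stack([a.ravel(), b.ravel(), c.ravel()], axis=1).astype(np.int32)

    full_j, full_k = np.arange(h), np.arange(d)
    inner_i = np.arange(1, w - 1)
    inner_j = np.arange(1, h - 1)
    add("x-", mesh([0], full_j, full_k))
    add("x+", mesh([w - 1], full_j, full_k))
    add("y-", mesh(inner_i, [0], full_k))
    add("y+", mesh(inner_i, [h - 1], full_k))
    add("z-", mesh(inner_i, inner_j, [0]))
    add("z+", mesh(inner_i, inner_j, [d - 1]))

    ijk = np.concatenate(faces_ijk, axis=0)
    cells = BoundaryCells(
        shape=(w, h, d),
        face_id=np.concatenate(face_ids),
        uv=np.concatenate(faces_uv, axis=0).astype(np.int32),
        ijk=ijk,
    )
    assert len(cells) == boundary_cell_count((w, h, d))
    return cells
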