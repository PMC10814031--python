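"""Pareto-front path selection and weighted ranking.

All objectives (R, L, A) are normalized to [0, 1] and maximized. A point y
strictly dominates x in a 2D projection iff y >= x on both axes and y > x on
at least one; duplicates of a non-dominated vector are all retained. The 2D
fronts are produced by a sort-and-prune sweep (sort descending by the first
objective, keep a point iff it improves the best second objective seen among
strictly better first objectives), which is contractually identical to the
O(n^2) dominance definition.

The global candidate set is the intersection of the three pairwise fronts
(R,L), (R,A), (L,A). That intersection can be empty — points may be
non-dominated in different projections — in which case the full 3D
non-dominated set is used instead (every 2D-front member is also 3D
non-dominated, so the 3D front is a superset of the intended set) and the
fallback is flagged in the result provenance.

Final ranking: G = λ1·R + λ2·L + λ3·A (weighted sum; a weighted-product
variant Π s^λ is available for sensitivity analysis), ties broken by
(R, L, A) descending then cell id ascending so results are independent of
input order.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


def pareto_front_2d(values: np.ndarray, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Indices of points not strictly dominated in the chosen objective pair.

    ``values`` is (N, k); both objectives are maximized. Duplicate objective
    vectors are all retained. Empty input yields an empty index array.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(0, dtype=np.int64)
    x = values[:, axes[0]]
    y = values[:, axes[1]]
    order = np.lexsort((-y, -x))  # descending by x, then by y
    keep = np.zeros(len(x), dtype=bool)
    best_y = -np.inf  # best y among points with strictly greater x
    i = 0
    n = len(order)
    while i < n:
        j = i
        xi = x[order[i]]
        group_best = -np.inf
        while j < n and x[order[j]] == xi:
            group_best = max(group_best, y[order[j]])
            j += 1
        if group_best > best_y:
            for k in range(i, j):
                if y[order[k]] == group_best:
                    keep[order[k]] = True
            best_y = group_best
        i = j
    return np.flatnonzero(keep)


def non_dominated_3d(values: np.ndarray) -> np.ndarray:
    """Indices of points not strictly dominated in all three objectives.

    Sweep in descending first objective; a staircase of (y, z) maxima over the
    strictly-better prefix answers the weak-dominance query in O(log n), so the
    whole maxima computation is O(n log n). Equal-x groups are resolved by the
    2D front on (y, z) before the group joins the staircase.
    """
    import bisect

    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    order = np.lexsort((-v[:, 2], -v[:, 1], -v[:, 0]))
    stair_y: list[float] = []  # ascending y, strictly descending z
    stair_z: list[float] = []
    keep = np.zeros(n, dtype=bool)

    def dominated_by_stair(y: float, z: float) -> bool:
        i = bisect.bisect_left(stair_y, y)
        return i < len(stair_y) and stair_z[i] >= z

    def insert(y: float, z: float) -> None:
        i = bisect.bisect_left(stair_y, y)
        if i < len(stair_y) and stair_z[i] >= z:
            return  # covered by an entry with y' >= y and z' >= z
        if i < len(stair_y) and stair_y[i] == y:
            stair_z[i] = z  # same y, higher z
        else:
            stair_y.insert(i, y)
            stair_z.insert(i, z)
        # entries with smaller y and z <= new z are now redundant
        j = i - 1
        while j >= 0 and stair_z[j] <= z:
            del stair_y[j]
            del stair_z[j]
            j -= 1

    i = 0
    while i < n:
        j = i
        x = v[order[i], 0]
        while j < n and v[order[j], 0] == x:
            j += 1
        group = order[i:j]
        survivors = group[pareto_front_2d(v[group][:, 1:], axes=(0, 1))]
        for g in survivors:
            if not dominated_by_stair(v[g, 1], v[g, 2]):
                keep[g] = True
        for g in group:
            insert(v[g, 1], v[g, 2])
        i = j
    return np.flatnonzero(keep)


def pareto_intersection(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Intersection of the three pairwise Pareto fronts.

    Returns (indices, fallback_used). When the intersection is empty the full
    3D non-dominated set is returned with ``fallback_used=True``.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return np.zeros(0, dtype=np.int64), False
    fronts = [set(pareto_front_2d(v, axes).tolist()) for axes in ((0, 1), (0, 2), (1, 2))]
    inter = fronts[0] & fronts[1] & fronts[2]
    if inter:
        return np.asarray(sorted(inter), dtype=np.int64), False
    return non_dominated_3d(v), True


def weighted_score(values: np.ndarray, weights, aggregate: str = "sum") -> np.ndarray:
    """Aggregate score G per point; weights must be non-negative and sum to 1."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < 0) or abs(float(w.sum()) - 1.0) > 1e-9:
        raise ConfigurationError("weights must be 3 non-negative reals summing to 1")
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if aggregate == "sum":
        g = v @ w
    elif aggregate == "product":
        g = np.prod(np.power(np.clip(v, 1e-300, None), w), axis=1)
    else:
        raise ConfigurationError(f"unknown aggregate {aggregate!r}")
    return g if np.asarray(values).ndim == 2 else float(g[0])


def select_top_k(
    cell_ids: np.ndarray,
    values: np.ndarray,
    weights,
    k: int,
    aggregate: str = "sum",
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Rank the Pareto candidates by G and keep the best min(k, front size).

    Returns (selected positions into the input arrays, their G scores,
    fallback_used, front size). Deterministic under any input permutation:
    ties in G are broken by (R, L, A) descending, then by cell id ascending.
    """
    cell_ids = np.asarray(cell_ids)
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0), False, 0
    front, fallback = pareto_intersection(values)
    g = np.asarray(weighted_score(values[front], weights, aggregate))
    fv = values[front]
    order = np.lexsort((cell_ids[front], -fv[:, 2], -fv[:, 1], -fv[:, 0], -g))
    order = order[: min(k, len(order))]
    return front[order], g[order], fallback, len(front)
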