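"""Built-in channel tracer: clearance grid + widest-bottleneck path search.

Tunnel-detection packages for real proteins (MOLE, CAVER) use Voronoi-based
machinery; at toy scale a regular grid of *clearance* values is simpler and
exact.  The clearance at a point p is

    clearance(p) = min_i ( ||p - atom_i|| - vdw_i )

i.e. the radius of the largest probe sphere centered at p that touches no
atom.  A channel is then the path from a start voxel to the padded-box
boundary that maximizes the minimum clearance along the way (the
*bottleneck*), over 26-connected voxels whose clearance is at least
``min_radius``.  The traced path's voxel centers with their clearances form
an ordinary :class:`~tunnelmetrics.channel_model.ChannelProfile`, ready for
frustum-sum measurement.

Two independent routes to the bottleneck value are provided:
:func:`trace_channel` (widest-path Dijkstra, returns the path) and
:func:`floodfill_bottleneck` (binary search over clearance thresholds with
connected-component labelling, value only), which serves as a
cross-check.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .channel_model import AtomSet, ChannelProfile, SphereNode
from .errors import TraceError, ValidationError

logger = logging.getLogger(__name__)

#: 26-neighbourhood offsets (all nonzero sign combinations), fixed order for determinism.
_NEIGHBOURS = np.array(
    [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)],
    dtype=int,
)


@dataclass(frozen=True)
class ClearanceGrid:
    """Regular grid of exact clearance values over the padded bounding box."""

    origin: np.ndarray  # (3,) Å, center of voxel (0,0,0)
    spacing: float  # Å
    values: np.ndarray  # (nx, ny, nz) clearance, Å

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_center(self, index: tuple[int, int, int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(index, dtype=float)

    def nearest_voxel(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = np.rint((np.asarray(point, dtype=float) - self.origin) / self.spacing)
        idx = np.clip(idx, 0, np.array(self.shape) - 1).astype(int)
        return tuple(int(i) for i in idx)

    def is_boundary(self, index: tuple[int, int, int]) -> bool:
        return any(i == 0 or i == n - 1 for i, n in zip(index, self.shape))


def _grid_points(origin: np.ndarray, shape: tuple[int, int, int], spacing: float) -> np.ndarray:
    axes = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


def clearance_at(atoms: AtomSet, points: np.ndarray) -> np.ndarray:
    """Brute-force clearance of arbitrary points: min over atoms of (distance - vdW)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.full(points.shape[0], np.inf)
    # chunked to bound memory on large grids
    for start in range(0, points.shape[0], 8192):
        chunk = points[start : start + 8192]
        d = np.linalg.norm(chunk[:, None, :] - atoms.coords[None, :, :], axis=2)
        out[start : start + 8192] = (d - atoms.radii[None, :]).min(axis=1)
    return out


def _clearance_kdtree(atoms: AtomSet, points: np.ndarray) -> np.ndarray:
    # exact: min_i(d_i - r_i) decomposes over groups of equal radius, and
    # within a group the minimizer is the nearest atom
    out = np.full(points.shape[0], np.inf)
    for r in np.unique(atoms.radii):
        subset = atoms.coords[atoms.radii == r]
        d, _ = cKDTree(subset).query(points)
        np.minimum(out, d - r, out=out)
    return out


def build_clearance_grid(
    atoms: AtomSet,
    spacing: float = 0.5,
    pad: float = 5.0,
    max_cells: int = 4_000_000,
    method: str = "kdtree",
) -> ClearanceGrid:
    """Compute the exact clearance field on the padded bounding-box grid.

    ``method`` selects ``"kdtree"`` (per-radius-group nearest-neighbour
    queries) or ``"brute"`` (direct minimum over all atoms); both give
    identical values.  Grids beyond ``max_cells`` voxels are refused with a
    hint to increase ``spacing``.
    """
    if not (0.25 <= spacing <= 2.0):
        raise ValidationError(f"spacing must lie in [0.25, 2.0] A, got {spacing}")
    if pad < 3.0:
        raise ValidationError(f"pad must be >= 3 A, got {pad}")
    lo = atoms.coords.min(axis=0) - pad
    hi = atoms.coords.max(axis=0) + pad
    shape = tuple(int(np.floor((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    n_cells = int(np.prod(shape))
    if n_cells > max_cells:
        raise ValidationError(
            f"grid of {shape} = {n_cells} voxels exceeds the cap of {max_cells}; "
            f"use a larger spacing"
        )
    points = _grid_points(lo, shape, spacing)
    if method == "brute":
        values = clearance_at(atoms, points)
    elif method == "kdtree":
        values = _clearance_kdtree(atoms, points)
    else:
        raise ValidationError(f"unknown clearance method {method!r}")
    return ClearanceGrid(origin=lo, spacing=spacing, values=values.reshape(shape))


def _widest_path(
    grid: ClearanceGrid, start: tuple[int, int, int], min_radius: float
) -> list[tuple[int, int, int]]:
    """Widest-bottleneck Dijkstra from ``start`` to any boundary voxel.

    Priority: larger bottleneck first, then fewer steps, then lexicographic
    voxel index — fully deterministic.
    """
    values = grid.values
    shape = np.array(values.shape)
    passable = values >= min_radius
    best_b = np.full(values.shape, -np.inf)
    best_steps = np.full(values.shape, np.iinfo(np.int64).max, dtype=np.int64)
    parent: dict[tuple[int, int, int], tuple[int, int, int]] = {}

    b0 = float(values[start])
    best_b[start] = b0
    best_steps[start] = 0
    heap: list[tuple[float, int, tuple[int, int, int]]] = [(-b0, 0, start)]
    goal: tuple[int, int, int] | None = None
    while heap:
        neg_b, steps, idx = heapq.heappop(heap)
        b = -neg_b
        if b < best_b[idx] or (b == best_b[idx] and steps > best_steps[idx]):
            continue  # stale entry
        if grid.is_boundary(idx):
            goal = idx
            break
        for off in _NEIGHBOURS:
            nxt = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
            if any(nxt[d] < 0 or nxt[d] >= shape[d] for d in range(3)):
                continue
            if not passable[nxt]:
                continue
            nb = min(b, float(values[nxt]))
            ns = steps + 1
            if nb > best_b[nxt] or (nb == best_b[nxt] and ns < best_steps[nxt]):
                best_b[nxt] = nb
                best_steps[nxt] = ns
                parent[nxt] = idx
                heapq.heappush(heap, (-nb, ns, nxt))
    if goal is None:
        raise TraceError("no channel found: start is not connected to the exterior")
    path = [goal]
    while path[-1] != start:
        path.append(parent[path[-1]])
    path.reverse()
    return path


def trace_channel(
    atoms: AtomSet,
    start: np.ndarray,
    spacing: float = 0.5,
    min_radius: float = 0.9,
    pad: float = 5.0,
    channel_id: str = "traced",
    grid: ClearanceGrid | None = None,
) -> ChannelProfile:
    """Trace the widest-bottleneck channel from ``start`` to the exterior.

    Returns the path's voxel centers with their clearance values as the
    channel profile.  ``min_radius`` (default 0.9 Å, roughly a water-sized
    probe minus slack) prunes voxels too narrow to be channel interior.
    Raises :class:`TraceError` with "start occluded" when the start voxel's
    clearance is below ``min_radius``, or "no channel found" when no
    passable path reaches the padded-box boundary.  A precomputed ``grid``
    (from :func:`build_clearance_grid` with the same atoms) may be passed to
    avoid recomputation.
    """
    if min_radius <= 0:
        raise ValidationError(f"min_radius must be > 0, got {min_radius}")
    if grid is None:
        grid = build_clearance_grid(atoms, spacing=spacing, pad=pad)
    start_idx = grid.nearest_voxel(np.asarray(start, dtype=float))
    if grid.values[start_idx] < min_radius:
        raise TraceError(
            f"start occluded: clearance {grid.values[start_idx]:.3f} A at the "
            f"start voxel is below min_radius {min_radius} A"
        )
    if grid.is_boundary(start_idx):
        raise TraceError(
            "start voxel lies on the exterior boundary; nothing to trace "
            "(increase pad or move the start inward)"
        )
    path = _widest_path(grid, start_idx, min_radius)
    logger.info(
        "traced channel: %d voxels, bottleneck %.3f A",
        len(path),
        min(float(grid.values[i]) for i in path),
    )
    nodes = tuple(
        SphereNode(*grid.voxel_center(i), float(grid.values[i])) for i in path
    )
    return ChannelProfile(channel_id, nodes)


def bottleneck_radius(profile: ChannelProfile) -> float:
    """Minimum local radius along a channel profile."""
    return min(n.r for n in profile.nodes)


def floodfill_bottleneck(
    grid: ClearanceGrid, start: tuple[int, int, int], min_radius: float
) -> float | None:
    """Bottleneck value by threshold search + connected-component labelling.

    Independent of the path search: for each candidate clearance threshold
    t the voxels with clearance >= t are labelled into 26-connected
    components, and t is feasible iff the start voxel's component touches
    the boundary.  Binary search over the sorted unique clearance values
    finds the largest feasible t.  Returns None when even ``min_radius`` is
    infeasible.
    """
    values = grid.values
    structure = np.ones((3, 3, 3), dtype=bool)

    def feasible(threshold: float) -> bool:
        mask = values >= threshold
        if not mask[start]:
            return False
        labels, _ = ndimage.label(mask, structure=structure)
        target = labels[start]
        boundary_labels = np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
        return bool(np.any(boundary_labels == target))

    candidates = np.unique(values[values >= min_radius])
    if candidates.size == 0 or not feasible(min_radius):
        return None
    lo, hi = 0, candidates.size - 1  # candidates[lo] known feasible after check below
    if not feasible(float(candidates[0])):
        return None
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if feasible(float(candidates[mid])):
            lo = mid
        else:
            hi = mid - 1
    return float(candidates[lo])
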