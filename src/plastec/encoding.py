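"""Chromosome encoding: from 8 genes to a pair of connected sub-regions.

A chromosome carries two mm-space points and two quantized size genes:
(X1, Y1, Z1, L1, X2, Y2, Z2, L2).  Each point is decoded to a *root voxel*
(the ROI voxel whose center is nearest in mm), and the sub-region is grown
from the root by breadth-first search over 6-neighbor adjacency restricted
to the ROI, taking the root plus the first L enqueued voxels.  Whenever BFS
must choose among several frontier voxels, the voxel with the smallest
z-coordinate wins, then y, then x — the same rule breaks nearest-root ties.
This makes decoding a pure, fully deterministic function of the genes.

The size genes live on a quantization lattice {L_min, L_min + L_step, ...}
capped at the ROI size (defaults L_min=64, L_step=5, i.e. sub-regions of at
least 4x4x4 voxels at production scale; tiny synthetic ROIs use a denser
lattice).  A sub-region has L+1 voxels (root included) unless the root's
connected component is smaller, in which case the whole component is taken.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .io import ROIDefinition, VoxelGrid

__all__ = [
    "Chromosome",
    "SubRegion",
    "SubRegionalPair",
    "LLattice",
    "ROISearchSpace",
    "decode_root_voxel",
    "grow_subregion_bfs",
    "decode_chromosome",
]

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.intp
)


@dataclasses.dataclass(frozen=True)
class Chromosome:
    """8-gene indirect encoding of a sub-regional pair.

    Spatial genes are mm coordinates inside the bounding cuboid of the
    respective ROI's voxel centers; L genes are integers on the quantization
    lattice.
    """

    x1: float
    y1: float
    z1: float
    l1: int
    x2: float
    y2: float
    z2: float
    l2: int

    @property
    def point_a(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.z1])

    @property
    def point_b(self) -> np.ndarray:
        return np.array([self.x2, self.y2, self.z2])


@dataclasses.dataclass(frozen=True)
class SubRegion:
    """A 6-connected set of ROI voxels grown from a root."""

    roi_name: str
    root_voxel: tuple[int, int, int]
    members: np.ndarray  # ROI row indices, root first

    def __len__(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class SubRegionalPair:
    """A decoded pair of sub-regions plus its fitness bookkeeping."""

    subA: SubRegion
    subB: SubRegion
    NC1: int | None = None
    NC2: int | None = None
    EC2: float | None = None
    SD: float | None = None
    Z: float | None = None
    fitness: float | None = None
    sign: int | None = None
    p_raw: float | None = None
    p_corrected: float | None = None
    level: int | None = None

    @property
    def TC(self) -> int:
        return len(self.subA) * len(self.subB)

    @property
    def delta(self) -> int:
        """Edges gained (positive) or lost (negative) from session 1 to 2."""
        return int(self.NC2 - self.NC1)


class LLattice:
    """Allowed values of a size gene: L_min, L_min+L_step, ... capped at ROI size."""

    def __init__(self, roi_size: int, l_min: int = 64, l_step: int = 5):
        if roi_size < 1:
            raise ValueError("ROI size must be positive")
        if l_min < 0 or l_step < 1:
            raise ValueError("need l_min >= 0 and l_step >= 1")
        values = np.arange(l_min, roi_size + 1, l_step, dtype=int)
        if len(values) == 0:
            values = np.array([roi_size], dtype=int)
        self.values = values

    def __len__(self) -> int:
        return len(self.values)

    def clamp_index(self, idx: int) -> int:
        return int(min(max(idx, 0), len(self.values) - 1))

    def index_of(self, value: int) -> int:
        hits = np.nonzero(self.values == value)[0]
        if len(hits) == 0:
            raise ValueError(f"{value} is not on the L lattice {self.values}")
        return int(hits[0])


class ROISearchSpace:
    """Precomputed decoding structures for one ROI on one grid.

    Holds the voxel centers (mm), the bounding cuboid, a KD-tree for root
    lookup, (z, y, x)-sorted 6-neighbor adjacency, the L lattice, and a cache
    of full BFS enqueue orders per root (the order is independent of L, so a
    sub-region of size L+1 is a prefix of the cached order).
    """

    def __init__(
        self,
        roi: ROIDefinition,
        grid: VoxelGrid,
        l_min: int = 64,
        l_step: int = 5,
    ):
        roi.check_in_bounds(grid)
        self.roi = roi
        self.grid = grid
        self.centers = grid.voxel_centers_mm(roi.voxels)
        self.bounds_lo = self.centers.min(axis=0)
        self.bounds_hi = self.centers.max(axis=0)
        self.lattice = LLattice(len(roi), l_min=l_min, l_step=l_step)
        self._tree = cKDTree(self.centers)

        # rank voxels by (z, y, x) mm center; ties in all three cannot occur
        # for distinct voxels under an invertible affine
        order = np.lexsort((self.centers[:, 0], self.centers[:, 1], self.centers[:, 2]))
        self._zyx_rank = np.empty(len(roi), dtype=np.intp)
        self._zyx_rank[order] = np.arange(len(roi))

        index_of = {tuple(v): i for i, v in enumerate(np.asarray(roi.voxels))}
        neighbors = []
        for v in np.asarray(roi.voxels):
            nbr = [index_of.get(tuple(v + off)) for off in _NEIGHBOR_OFFSETS]
            nbr = np.array([n for n in nbr if n is not None], dtype=np.intp)
            neighbors.append(nbr[np.argsort(self._zyx_rank[nbr])] if len(nbr) else nbr)
        self._neighbors = neighbors
        self._bfs_cache: dict[int, np.ndarray] = {}

    def nearest_root(self, point_mm: np.ndarray) -> int:
        """ROI row index of the voxel center nearest to ``point_mm`` (mm).

        Ties are broken by smallest (z, y, x) center coordinate.
        """
        point_mm = np.asarray(point_mm, dtype=float)
        d, idx = self._tree.query(point_mm)
        ball = self._tree.query_ball_point(point_mm, d + 1e-7)
        if len(ball) <= 1:
            return int(idx)
        ball = np.asarray(ball, dtype=np.intp)
        dists = np.linalg.norm(self.centers[ball] - point_mm, axis=1)
        ties = ball[dists <= d + 1e-9]
        return int(ties[np.argmin(self._zyx_rank[ties])])

    def nearest_roots_batch(self, points_mm: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`nearest_root` for an (n, 3) array of points.

        Unambiguous nearest neighbours come from one batched KD-tree query;
        near-ties fall back to the exact tie-break rule.
        """
        points_mm = np.asarray(points_mm, dtype=float)
        k = min(2, len(self.roi))
        d, idx = self._tree.query(points_mm, k=k)
        if k == 1:
            return np.atleast_1d(idx)
        out = idx[:, 0].copy()
        for i in np.flatnonzero(d[:, 1] - d[:, 0] < 1e-9):
            out[i] = self.nearest_root(points_mm[i])
        return out

    def bfs_order(self, root: int) -> np.ndarray:
        """Full deterministic BFS enqueue order from ``root`` (root first)."""
        cached = self._bfs_cache.get(root)
        if cached is not None:
            return cached
        visited = np.zeros(len(self.roi), dtype=bool)
        order = np.empty(len(self.roi), dtype=np.intp)
        order[0] = root
        visited[root] = True
        head, tail = 0, 1
        while head < tail:
            v = order[head]
            head += 1
            for nb in self._neighbors[v]:
                if not visited[nb]:
                    visited[nb] = True
                    order[tail] = nb
                    tail += 1
        out = order[:tail].copy()
        out.setflags(write=False)
        self._bfs_cache[root] = out
        return out

    def members(self, root: int, L: int) -> np.ndarray:
        """Root plus the first L BFS-enqueued voxels (capped by component size)."""
        order = self.bfs_order(root)
        return order[: L + 1]

    def subregion(self, root: int, L: int) -> SubRegion:
        return SubRegion(
            roi_name=self.roi.name,
            root_voxel=tuple(int(c) for c in self.roi.voxels[root]),
            members=self.members(root, L),
        )


def decode_root_voxel(
    point_mm: np.ndarray, roi: ROIDefinition | ROISearchSpace, grid: VoxelGrid | None = None
) -> tuple[int, int, int]:
    """The ROI voxel whose center (mm) is nearest to ``point_mm``."""
    space = roi if isinstance(roi, ROISearchSpace) else ROISearchSpace(roi, grid, l_min=0, l_step=1)
    idx = space.nearest_root(point_mm)
    return tuple(int(c) for c in space.roi.voxels[idx])


def grow_subregion_bfs(
    root: tuple[int, int, int],
    roi: ROIDefinition | ROISearchSpace,
    L: int,
    grid: VoxelGrid | None = None,
) -> SubRegion:
    """Grow a sub-region of (up to) L+1 voxels from ``root`` by deterministic BFS."""
    if L < 0:
        raise ValueError("L must be >= 0")
    space = roi if isinstance(roi, ROISearchSpace) else ROISearchSpace(roi, grid, l_min=0, l_step=1)
    root_idx = space.roi.index_of.get(tuple(int(c) for c in root))
    if root_idx is None:
        raise ValueError(f"root voxel {root} is not part of ROI {space.roi.name!r}")
    return space.subregion(root_idx, L)


def decode_chromosome(
    c: Chromosome,
    roiA: ROIDefinition | ROISearchSpace,
    roiB: ROIDefinition | ROISearchSpace,
    grid: VoxelGrid | None = None,
    l_min: int = 64,
    l_step: int = 5,
) -> SubRegionalPair:
    """Decode a chromosome into its sub-regional pair (geometry only)."""
    spaceA = roiA if isinstance(roiA, ROISearchSpace) else ROISearchSpace(roiA, grid, l_min, l_step)
    spaceB = roiB if isinstance(roiB, ROISearchSpace) else ROISearchSpace(roiB, grid, l_min, l_step)
    rootA = spaceA.nearest_root(c.point_a)
    rootB = spaceB.nearest_root(c.point_b)
    return SubRegionalPair(
        subA=spaceA.subregion(rootA, int(c.l1)),
        subB=spaceB.subregion(rootB, int(c.l2)),
    )
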