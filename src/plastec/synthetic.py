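"""Synthetic two-session data with planted plastic sub-regional pairs.

Two entry points share one ground-truth description (:class:`PlantedTruth`):

* the **matrix generator** draws binary connectivity matrices directly, so
  the evolutionary search can be tested in isolation from the
  correlation/FDR stage.  Every cell gets one uniform draw shared by both
  sessions and is an edge in session s iff the draw falls below the cell's
  session-s density (background, or the planted block's density).  This
  common-random-numbers coupling models session-to-session edge
  persistence: equal densities give identical matrices, and a density
  increase adds edges without removing any.
* the **time-series generator** adds a per-block latent signal to the member
  voxels of both ROIs with a session-specific coupling amplitude on top of
  i.i.d. Gaussian noise, which induces the block-structured positive
  correlations the detection pipeline assumes.

Planted sub-regions are grown with the same deterministic BFS rule the
chromosome decoder uses, so each planted block is exactly representable by
some chromosome and recovery is well posed.  Default sizes are desk-scale
stand-ins for the production setting (ROIs of hundreds to ~1800 voxels,
145 volumes per session on a 3 mm isotropic grid): T keeps the production
value of 145; ROI sizes default to 120 and 150 voxels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .encoding import ROISearchSpace
from .io import ROIDefinition, SessionTimeSeries, VoxelGrid

__all__ = [
    "PlantedBlock",
    "PlantedTruth",
    "make_geometry",
    "plant_block",
    "make_matrix_dataset",
    "make_timeseries_dataset",
    "preset_matrix_subject",
    "preset_timeseries_subject",
]

_NEIGHBOR_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclasses.dataclass(frozen=True)
class PlantedBlock:
    """One planted sub-regional pair with its per-session signal levels.

    For the matrix generator, ``density1/density2`` are Bernoulli edge
    probabilities; for the time-series generator, ``coupling1/coupling2``
    are latent-signal amplitudes (in units of the noise SD).
    """

    a_members: np.ndarray  # ROI-A row indices, 6-connected
    b_members: np.ndarray  # ROI-B row indices, 6-connected
    density1: float | None = None
    density2: float | None = None
    coupling1: float | None = None
    coupling2: float | None = None

    @property
    def sign(self) -> int:
        s1 = self.density1 if self.density1 is not None else self.coupling1
        s2 = self.density2 if self.density2 is not None else self.coupling2
        return int(np.sign(s2 - s1))

    @property
    def n_edges(self) -> int:
        return len(self.a_members) * len(self.b_members)


@dataclasses.dataclass(frozen=True)
class PlantedTruth:
    blocks: list[PlantedBlock]
    background_density: float = 0.03
    noise_sd: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        seen_a: set[int] = set()
        for blk in self.blocks:
            a = set(int(v) for v in blk.a_members)
            if a & seen_a:
                # disjoint A-side sub-regions guarantee disjoint edge supports
                raise ValueError("planted blocks must have disjoint edge supports")
            seen_a |= a


def _grow_random_region(
    shape: tuple[int, int, int],
    size: int,
    forbidden: set[tuple[int, int, int]],
    rng: np.random.Generator,
) -> list[tuple[int, int, int]] | None:
    """Randomized region growing: connected set of ``size`` voxels avoiding
    ``forbidden``; None if growth stalls."""
    free = [
        (i, j, k)
        for i in range(shape[0])
        for j in range(shape[1])
        for k in range(shape[2])
        if (i, j, k) not in forbidden
    ]
    if not free:
        return None
    start = free[rng.integers(len(free))]
    region = {start}
    frontier = [start]
    while len(region) < size:
        if not frontier:
            return None
        idx = rng.integers(len(frontier))
        v = frontier[idx]
        candidates = [
            (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            for o in _NEIGHBOR_OFFSETS
        ]
        candidates = [
            c
            for c in candidates
            if all(0 <= c[d] < shape[d] for d in range(3))
            and c not in region
            and c not in forbidden
        ]
        if not candidates:
            frontier.pop(idx)
            continue
        new = candidates[rng.integers(len(candidates))]
        region.add(new)
        frontier.append(new)
    return sorted(region)


def make_geometry(
    shape: tuple[int, int, int] = (12, 12, 12),
    roi_sizes: tuple[int, int] = (120, 150),
    rng: np.random.Generator | int | None = None,
    voxel_size_mm: float = 3.0,
    max_tries: int = 50,
) -> tuple[VoxelGrid, ROIDefinition, ROIDefinition]:
    """Two disjoint 6-connected ROIs grown by randomized BFS on a 3D grid."""
    rng = np.random.default_rng(rng)
    if sum(roi_sizes) > int(np.prod(shape)):
        raise ValueError(f"ROI sizes {roi_sizes} do not fit in grid {shape}")
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    grid = VoxelGrid(shape=shape, affine=affine)
    for _ in range(max_tries):
        vox_a = _grow_random_region(shape, roi_sizes[0], set(), rng)
        if vox_a is None:
            continue
        vox_b = _grow_random_region(shape, roi_sizes[1], set(vox_a), rng)
        if vox_b is None:
            continue
        roi_a = ROIDefinition(name="ROI-A", voxels=np.array(vox_a))
        roi_b = ROIDefinition(name="ROI-B", voxels=np.array(vox_b))
        return grid, roi_a, roi_b
    raise RuntimeError(f"could not fit disjoint connected ROIs of sizes {roi_sizes} in {shape}")


def plant_block(
    spaceA: ROISearchSpace,
    spaceB: ROISearchSpace,
    size_a: int,
    size_b: int,
    rng: np.random.Generator,
    avoid_a: set[int] | None = None,
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick a decodable planted sub-region pair (deterministic BFS growth
    from random roots); the A side avoids voxels of earlier blocks."""
    avoid_a = avoid_a or set()
    for _ in range(max_tries):
        root_a = int(rng.integers(len(spaceA.roi)))
        a_members = spaceA.members(root_a, size_a - 1)
        if len(a_members) < size_a or (set(a_members.tolist()) & avoid_a):
            continue
        root_b = int(rng.integers(len(spaceB.roi)))
        b_members = spaceB.members(root_b, size_b - 1)
        if len(b_members) < size_b:
            continue
        return np.asarray(a_members), np.asarray(b_members)
    raise RuntimeError("could not place a planted block with disjoint A-side support")


def make_matrix_dataset(
    truth: PlantedTruth,
    roiA: ROIDefinition,
    roiB: ROIDefinition,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary session matrices with planted block densities over a Bernoulli
    background, coupled across sessions by common random numbers."""
    rng = np.random.default_rng(rng)
    u = rng.random((len(roiA), len(roiB)))
    m1 = u < truth.background_density
    m2 = u < truth.background_density
    for blk in truth.blocks:
        if blk.density1 is None or blk.density2 is None:
            raise ValueError("matrix generator needs density1/density2 on every block")
        sub = np.ix_(blk.a_members, blk.b_members)
        m1[sub] = u[sub] < blk.density1
        m2[sub] = u[sub] < blk.density2
    return m1.astype(np.uint8), m2.astype(np.uint8)


def make_timeseries_dataset(
    truth: PlantedTruth,
    roiA: ROIDefinition,
    roiB: ROIDefinition,
    T: int = 145,
    rng: np.random.Generator | int | None = None,
) -> dict[tuple[str, int], SessionTimeSeries]:
    """Per-ROI per-session voxel time series with planted latent couplings.

    Each block has one latent signal per session; member voxels of both ROIs
    receive ``coupling_s * latent`` on top of i.i.d. Gaussian noise of SD
    ``truth.noise_sd``.  Higher session-2 coupling yields positive
    plasticity through the full correlation/FDR pipeline.
    """
    rng = np.random.default_rng(rng)
    out: dict[tuple[str, int], SessionTimeSeries] = {}
    for session in (1, 2):
        data_a = rng.normal(scale=truth.noise_sd, size=(len(roiA), T))
        data_b = rng.normal(scale=truth.noise_sd, size=(len(roiB), T))
        for blk in truth.blocks:
            if blk.coupling1 is None or blk.coupling2 is None:
                raise ValueError("time-series generator needs coupling1/coupling2 on every block")
            c = blk.coupling1 if session == 1 else blk.coupling2
            latent = rng.normal(size=T)
            data_a[blk.a_members] += c * latent
            data_b[blk.b_members] += c * latent
        out[(roiA.name, session)] = SessionTimeSeries(session_id=session, data=data_a)
        out[(roiB.name, session)] = SessionTimeSeries(session_id=session, data=data_b)
    return out


# ---------------------------------------------------------------------------
# canonical desk-scale subjects


def preset_matrix_subject(
    seed: int,
    shape: tuple[int, int, int] = (12, 12, 12),
    roi_sizes: tuple[int, int] = (120, 150),
    block_sizes: tuple[int, int] = (40, 60),
    density1: float = 0.05,
    density2: float = 0.9,
    background_density: float = 0.03,
):
    """One gaining planted block on a random geometry; matrix-level data.

    Returns (grid, roiA, roiB, truth, M1, M2).  The defaults plant a block
    covering ~13% of all ROI-pair edges that jumps from 5% to 90% density
    between sessions against a 3% background.
    """
    rng = np.random.default_rng(seed)
    grid, roi_a, roi_b = make_geometry(shape, roi_sizes, rng)
    space_a = ROISearchSpace(roi_a, grid, l_min=1, l_step=1)
    space_b = ROISearchSpace(roi_b, grid, l_min=1, l_step=1)
    a_m, b_m = plant_block(space_a, space_b, *block_sizes, rng)
    truth = PlantedTruth(
        blocks=[
            PlantedBlock(a_members=a_m, b_members=b_m, density1=density1, density2=density2)
        ],
        background_density=background_density,
        rng_seed=seed,
    )
    m1, m2 = make_matrix_dataset(truth, roi_a, roi_b, rng)
    return grid, roi_a, roi_b, truth, m1, m2


def preset_timeseries_subject(
    seed: int,
    shape: tuple[int, int, int] = (10, 10, 10),
    roi_sizes: tuple[int, int] = (60, 80),
    block_sizes: tuple[int, int] = (25, 35),
    coupling1: float = 0.0,
    coupling2: float = 1.5,
    T: int = 145,
):
    """One gaining planted block; full time-series data for the pipeline.

    Returns (grid, roiA, roiB, truth, series) where series maps
    (roi_name, session) -> SessionTimeSeries.
    """
    rng = np.random.default_rng(seed)
    grid, roi_a, roi_b = make_geometry(shape, roi_sizes, rng)
    space_a = ROISearchSpace(roi_a, grid, l_min=1, l_step=1)
    space_b = ROISearchSpace(roi_b, grid, l_min=1, l_step=1)
    a_m, b_m = plant_block(space_a, space_b, *block_sizes, rng)
    truth = PlantedTruth(
        blocks=[
            PlantedBlock(a_members=a_m, b_members=b_m, coupling1=coupling1, coupling2=coupling2)
        ],
        rng_seed=seed,
    )
    series = make_timeseries_dataset(truth, roi_a, roi_b, T=T, rng=rng)
    return grid, roi_a, roi_b, truth, series
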