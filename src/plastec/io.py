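"""Reading two-session voxel time series and ROI definitions on a common grid.

All spatial bookkeeping lives here: the voxel grid (shape + affine), ROI
definitions as ordered voxel lists with a stable voxel->index bijection, and
per-ROI per-session time-series matrices.  Row/column identity of every
connectivity matrix downstream depends on the ROI voxel order fixed at load
time, so the order is deterministic: ascending i, then j, then k (numpy
``argwhere`` lexicographic order over the label volume).

Voxel indices are 0-based throughout; the affine maps (i, j, k) voxel indices
to scanner mm coordinates, which is the space in which chromosome genes and
mutation offsets are expressed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "ROIDefinition",
    "SessionTimeSeries",
    "GridMismatchError",
    "load_inputs",
    "extract_roi_timeseries",
    "roi_from_label_volume",
    "read_roi_table",
    "write_roi_table",
    "write_srp_label_map",
]

_AFFINE_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Raised when two volumes disagree in shape or affine."""


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """A 3D sampling grid shared by all volumes of one analysis.

    Parameters
    ----------
    shape : tuple of int
        Grid dimensions (nx, ny, nz).
    affine : ndarray, shape (4, 4)
        Maps 0-based voxel indices (i, j, k, 1) to mm coordinates.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_centers_mm(self, ijk: np.ndarray) -> np.ndarray:
        """mm coordinates of the centers of voxels ``ijk`` (n, 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]

    def matches(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=_AFFINE_ATOL, rtol=0.0
        )


@dataclasses.dataclass(frozen=True)
class ROIDefinition:
    """An ordered set of distinct voxels defining one region of interest.

    ``voxels[v]`` is the grid coordinate of matrix row/column ``v``; the
    implied voxel->index map is a bijection that stays fixed for the whole
    pipeline.
    """

    name: str
    voxels: np.ndarray  # (n, 3) int

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.intp)
        if vox.ndim != 2 or vox.shape[1] != 3:
            raise ValueError("voxels must be an (n, 3) array of (i, j, k) triples")
        if len(vox) == 0:
            raise ValueError(f"ROI {self.name!r} has no voxels")
        if len(np.unique(vox, axis=0)) != len(vox):
            raise ValueError(f"ROI {self.name!r} contains duplicate voxels")
        object.__setattr__(self, "voxels", vox)

    def __len__(self) -> int:
        return len(self.voxels)

    @property
    def index_of(self) -> dict[tuple[int, int, int], int]:
        """Voxel (i, j, k) -> row/column index."""
        return {tuple(int(c) for c in v): i for i, v in enumerate(self.voxels)}

    def check_in_bounds(self, grid: VoxelGrid) -> None:
        if (self.voxels < 0).any() or (self.voxels >= np.array(grid.shape)).any():
            bad = self.voxels[
                ((self.voxels < 0) | (self.voxels >= np.array(grid.shape))).any(axis=1)
            ]
            raise ValueError(
                f"ROI {self.name!r} has voxels outside grid {grid.shape}: {bad.tolist()[:5]}"
            )


@dataclasses.dataclass(frozen=True)
class SessionTimeSeries:
    """BOLD samples for one ROI in one session; rows follow the ROI order."""

    session_id: int
    data: np.ndarray  # (n_voxels, T)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("time-series data must be 2-D (voxels x time)")
        if data.shape[1] < 3:
            raise ValueError(
                f"need at least 3 time points for correlation p-values, got {data.shape[1]}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _grid_of(img: nib.spatialimages.SpatialImage) -> VoxelGrid:
    return VoxelGrid(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def _check_same_grid(name_a: str, grid_a: VoxelGrid, name_b: str, grid_b: VoxelGrid) -> None:
    if grid_a.shape != grid_b.shape:
        raise GridMismatchError(
            f"shape mismatch: {name_a} has {grid_a.shape}, {name_b} has {grid_b.shape}"
        )
    if not np.allclose(grid_a.affine, grid_b.affine, atol=_AFFINE_ATOL, rtol=0.0):
        raise GridMismatchError(
            f"affine mismatch between {name_a} and {name_b}:\n"
            f"{grid_a.affine}\nvs\n{grid_b.affine}"
        )


def roi_from_label_volume(labels: np.ndarray, label: int, name: str | None = None) -> ROIDefinition:
    """Extract one ROI from an integer label volume.

    Voxel order is the deterministic raster order of ``np.argwhere``:
    ascending i, then j, then k.
    """
    labels = np.asarray(labels)
    vox = np.argwhere(labels == label)
    if len(vox) == 0:
        raise ValueError(f"label {label} not present in label volume")
    return ROIDefinition(name=name or f"label-{label}", voxels=vox)


def extract_roi_timeseries(
    volume4d: np.ndarray, roi: ROIDefinition, session_id: int = 1
) -> SessionTimeSeries:
    """Pull the (n_voxels, T) time-series matrix of ``roi`` out of a 4D volume.

    Row ``v`` of the result is the time course of ``roi.voxels[v]``.
    """
    volume4d = np.asarray(volume4d)
    if volume4d.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {volume4d.shape}")
    if (roi.voxels < 0).any() or (roi.voxels >= np.array(volume4d.shape[:3])).any():
        raise ValueError(f"ROI {roi.name!r} has voxels outside volume {volume4d.shape[:3]}")
    i, j, k = roi.voxels.T
    data = volume4d[i, j, k, :].astype(float)
    bad = ~np.isfinite(data).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite time series in ROI {roi.name!r} at voxels "
            f"{roi.voxels[bad].tolist()[:10]}"
        )
    return SessionTimeSeries(session_id=session_id, data=data)


def load_inputs(
    session1_path: str | Path,
    session2_path: str | Path,
    labels_path: str | Path,
    roi_a_label: int,
    roi_b_label: int,
    roi_a_name: str = "ROI-A",
    roi_b_name: str = "ROI-B",
):
    """Load the full input set for one subject / one ROI pair.

    Returns
    -------
    grid : VoxelGrid
    (roi_a, roi_b) : tuple of ROIDefinition
    series : dict
        ``{(roi_name, session_id): SessionTimeSeries}`` for both ROIs and
        both sessions.
    """
    img1 = nib.load(str(session1_path))
    img2 = nib.load(str(session2_path))
    lab_img = nib.load(str(labels_path))

    grid = _grid_of(img1)
    _check_same_grid("session-1", grid, "session-2", _grid_of(img2))
    _check_same_grid("session-1", grid, "labels", _grid_of(lab_img))

    labels = np.asarray(lab_img.dataobj).round().astype(int)
    roi_a = roi_from_label_volume(labels, roi_a_label, roi_a_name)
    roi_b = roi_from_label_volume(labels, roi_b_label, roi_b_name)

    vol1 = np.asarray(img1.dataobj, dtype=float)
    vol2 = np.asarray(img2.dataobj, dtype=float)
    if vol1.ndim != 4 or vol2.ndim != 4:
        raise ValueError("session volumes must be 4D BOLD series")
    if vol1.shape[3] != vol2.shape[3]:
        raise GridMismatchError(
            f"session volumes differ in number of time points: {vol1.shape[3]} vs {vol2.shape[3]}"
        )

    series = {}
    for roi in (roi_a, roi_b):
        series[(roi.name, 1)] = extract_roi_timeseries(vol1, roi, session_id=1)
        series[(roi.name, 2)] = extract_roi_timeseries(vol2, roi, session_id=2)
    return grid, (roi_a, roi_b), series


# ---------------------------------------------------------------------------
# plain-text ROI tables and SRP label maps


def write_roi_table(path: str | Path, rois: list[ROIDefinition]) -> None:
    """Write ROIs as a TSV with columns roi, i, j, k (one row per voxel)."""
    frames = [
        pd.DataFrame({"roi": roi.name, "i": roi.voxels[:, 0], "j": roi.voxels[:, 1], "k": roi.voxels[:, 2]})
        for roi in rois
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_roi_table(path: str | Path) -> list[ROIDefinition]:
    df = pd.read_csv(path, sep="\t")
    rois = []
    for name, grp in df.groupby("roi", sort=False):
        rois.append(ROIDefinition(name=str(name), voxels=grp[["i", "j", "k"]].to_numpy()))
    return rois


def write_srp_label_map(
    path: str | Path,
    grid: VoxelGrid,
    roi: ROIDefinition,
    member_lists: list[np.ndarray],
) -> None:
    """Write an integer NIfTI volume labelling each SRP's sub-region in ``roi``.

    ``member_lists[s]`` holds ROI row indices of SRP ``s+1``; label 0 is
    background.  Later SRPs overwrite earlier ones only where sub-regions
    overlap (they can, across recursion levels, on the voxel level).
    """
    vol = np.zeros(grid.shape, dtype=np.int16)
    for s, members in enumerate(member_lists, start=1):
        vox = roi.voxels[np.asarray(members, dtype=np.intp)]
        vol[vox[:, 0], vox[:, 1], vox[:, 2]] = s
    nib.save(nib.Nifti1Image(vol, grid.affine), str(path))


def read_srp_label_map(path: str | Path) -> tuple[VoxelGrid, dict[int, np.ndarray]]:
    """Inverse of :func:`write_srp_label_map`: label -> (n, 3) voxel array."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj).round().astype(int)
    grid = _grid_of(img)
    out = {}
    for lab in np.unique(vol):
        if lab == 0:
            continue
        out[int(lab)] = np.argwhere(vol == lab)
    return grid, out


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
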