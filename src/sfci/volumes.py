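"""Volumetric data containers, NIfTI I/O, and ROI transfer between co-registered spaces.

All voxel indices are 0-based. World coordinates follow the NIfTI affine
convention: ``world = affine @ [i, j, k, 1]``. ROI transfer maps voxel
*centers* through the affine chain and assigns each to the nearest
destination voxel, matching nearest-neighbour interpolation semantics.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import FrozenSet, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "TimeSeriesVolume",
    "SeedROI",
    "AffinePair",
    "VolumeFormatError",
    "EmptyROIError",
    "read_volume",
    "write_volume",
    "read_affine",
    "write_affine",
    "transfer_roi",
]

VoxelIndex = Tuple[int, int, int]


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as NIfTI or violates a grid invariant."""


class EmptyROIError(ValueError):
    """Raised when an operation would produce or consume an empty ROI."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclasses.dataclass
class VoxelGrid:
    """A 3-D scalar lattice with its grid-to-world affine.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field. Units given by `units`.
    affine : ndarray, shape (4, 4)
        Grid-to-world matrix (NIfTI convention).
    units : str
        Free-text unit label, e.g. ``"mm2/s"``, ``"z"``, ``"probability"``,
        ``"binary"``. Grids labelled ``"binary"`` may contain only {0, 1};
        grids labelled ``"probability"`` must lie in [0, 1].
    """

    values: np.ndarray
    affine: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VoxelGrid requires 3-D values, got ndim={self.values.ndim}")
        self.affine = _check_affine(self.affine)
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel size must be strictly positive")
        if self.units == "binary":
            if not np.isin(self.values, (0, 1)).all():
                raise ValueError("binary grid contains values outside {0, 1}")
        elif self.units == "probability":
            if self.values.min() < 0 or self.values.max() > 1:
                raise ValueError("probability grid contains values outside [0, 1]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Edge lengths in mm: column norms of the linear part of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates of voxel centers."""
        ijk = np.atleast_2d(np.asarray(indices, dtype=float))
        homog = np.column_stack([ijk, np.ones(len(ijk))])
        return (self.affine @ homog.T).T[:, :3]

    def in_bounds(self, index: VoxelIndex) -> bool:
        return all(0 <= index[d] < self.shape[d] for d in range(3))


@dataclasses.dataclass
class TimeSeriesVolume:
    """A 4-D (x, y, z, t) lattice with repetition time in seconds."""

    values: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"TimeSeriesVolume requires 4-D values, got ndim={self.values.ndim}")
        if self.values.shape[3] < 2:
            raise ValueError("time series needs at least 2 volumes")
        self.affine = _check_affine(self.affine)
        self.tr_s = float(self.tr_s)
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive; supply tr_s explicitly if the header TR is 0")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[3]

    @property
    def shape(self) -> Tuple[int, int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def spatial_grid(self, units: str = "") -> VoxelGrid:
        """The first volume's spatial lattice (useful for bounds/affine queries)."""
        return VoxelGrid(self.values[..., 0], self.affine, units=units)


@dataclasses.dataclass(frozen=True)
class SeedROI:
    """A set of 0-based voxel indices in a named space.

    The ``eroded`` flag marks ROIs that lost voxels to grey-matter masking or
    grid clipping (the deterministic replacement for manual erosion of seeds
    that intrude on intragyral CSF).
    """

    voxel_indices: FrozenSet[VoxelIndex]
    space: str
    role: str = "seed"
    hemisphere: str = "bilateral"
    pathway_name: str = ""
    eroded: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxel_indices",
                           frozenset(tuple(int(c) for c in v) for v in self.voxel_indices))
        if not self.voxel_indices:
            raise EmptyROIError(f"empty ROI in space '{self.space}'")

    def __len__(self) -> int:
        return len(self.voxel_indices)

    def as_array(self) -> np.ndarray:
        """Indices as an (n, 3) int array, sorted lexicographically."""
        return np.array(sorted(self.voxel_indices), dtype=int)

    def to_mask(self, grid: VoxelGrid) -> VoxelGrid:
        mask = np.zeros(grid.shape, dtype=np.uint8)
        idx = self.as_array()
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        return VoxelGrid(mask, grid.affine, units="binary")


@dataclasses.dataclass
class AffinePair:
    """A world-coordinate affine mapping one named space into another."""

    source_space: str
    dest_space: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = _check_affine(self.matrix)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path, units: str = "", tr_s: float | None = None):
    """Read a NIfTI file as a :class:`VoxelGrid` (3-D) or :class:`TimeSeriesVolume` (4-D).

    For 4-D files the repetition time comes from the header; a header TR of 0
    (common in malformed files) is rejected unless ``tr_s`` is supplied,
    because temporal filtering requires a trusted sampling rate.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    affine = img.affine
    if data.ndim == 3:
        return VoxelGrid(data, affine, units=units)
    if data.ndim == 4:
        if tr_s is None:
            zooms = img.header.get_zooms()
            tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr_s > 0:
            raise VolumeFormatError(
                f"{path}: header TR is {tr_s}; pass tr_s explicitly for 4-D volumes "
                "with an untrusted header")
        return TimeSeriesVolume(data, affine, tr_s=tr_s)
    raise VolumeFormatError(f"{path}: expected 3-D or 4-D data, got ndim={data.ndim}")


def write_volume(vol, path) -> None:
    """Write a VoxelGrid or TimeSeriesVolume to NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), vol.affine)
    if isinstance(vol, TimeSeriesVolume):
        zooms = list(img.header.get_zooms())
        zooms = zooms[:3] + [vol.tr_s]
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_affine(path) -> np.ndarray:
    """Read a 4x4 whitespace-delimited affine from a text file."""
    mat = np.loadtxt(path, dtype=float)
    if mat.shape == (3, 4):  # some tools omit the homogeneous row
        mat = np.vstack([mat, [0.0, 0.0, 0.0, 1.0]])
    return _check_affine(mat)


def write_affine(matrix: np.ndarray, path) -> None:
    np.savetxt(path, _check_affine(matrix), fmt="%.17g")


# ---------------------------------------------------------------------------
# ROI transfer
# ---------------------------------------------------------------------------

def transfer_roi(roi: SeedROI, pair: AffinePair, src_grid: VoxelGrid,
                 dest_grid: VoxelGrid) -> SeedROI:
    """Map an ROI into a co-registered space by nearest-neighbour assignment.

    Each source voxel center is mapped ``dest_vox = A_dest^-1 · M · A_src · src_vox``
    (A = grid-to-world affines, M = the world-coordinate transform of `pair`)
    and rounded to the nearest destination voxel; duplicates collapse.

    Raises
    ------
    EmptyROIError
        If every mapped voxel falls outside the destination grid.
    """
    if roi.space != pair.source_space:
        raise ValueError(
            f"ROI space '{roi.space}' does not match transform source '{pair.source_space}'")
    src = roi.as_array().astype(float)
    homog = np.column_stack([src, np.ones(len(src))])
    world = (pair.matrix @ src_grid.affine @ homog.T)
    dest = np.linalg.inv(dest_grid.affine) @ world
    dest_idx = np.round(dest[:3].T).astype(int)
    shape = np.array(dest_grid.shape)
    keep = np.all((dest_idx >= 0) & (dest_idx < shape), axis=1)
    kept = dest_idx[keep]
    if kept.size == 0:
        raise EmptyROIError(
            f"ROI '{roi.pathway_name or roi.role}' maps entirely outside space "
            f"'{pair.dest_space}'")
    return SeedROI(
        voxel_indices=frozenset(map(tuple, kept.tolist())),
        space=pair.dest_space,
        role=roi.role,
        hemisphere=roi.hemisphere,
        pathway_name=roi.pathway_name,
        eroded=roi.eroded or not bool(keep.all()),
    )
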