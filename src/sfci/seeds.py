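"""Seed and target construction for the three connectivity pathways.

The motor pathway (transcallosal SMC) is seeded at the activation peak of a
block-design finger-tapping task; the cognitive pathway (PCC-AMTL, one per
hemisphere) is seeded from an anatomically placed PCC sphere plus the
maximally correlated PCC/AMTL voxel pair in the resting-state series.

Manual gyral/CSF erosion of seeds is replaced by deterministic intersection
with a supplied grey-matter mask; ROIs that lose voxels carry an ``eroded``
flag. All tie-breaks are lexicographic on (x, y, z) voxel index so results
are identical across platforms.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Tuple

import numpy as np

from .volumes import EmptyROIError, SeedROI, TimeSeriesVolume, VoxelGrid

__all__ = [
    "ActivationMap",
    "PathwaySpec",
    "DesignError",
    "fit_boxcar_glm",
    "boxcar_design",
    "peak_voxel",
    "sphere_roi",
    "inplane_square_roi",
    "max_corr_pair",
]


class DesignError(ValueError):
    """Raised for rank-deficient or infeasible GLM designs."""


@dataclasses.dataclass
class ActivationMap:
    """Whole-brain Student's t map from a task GLM."""

    tmap: VoxelGrid
    dof: int
    task_label: str = ""

    def __post_init__(self) -> None:
        if self.dof < 1:
            raise ValueError("dof must be >= 1")


@dataclasses.dataclass
class PathwaySpec:
    """A named pathway: seed ROI, target ROI, and its track probability map."""

    name: str
    seed: SeedROI
    target: SeedROI
    track_map: VoxelGrid

    def __post_init__(self) -> None:
        if self.seed.space == self.target.space and (
                self.seed.voxel_indices & self.target.voxel_indices):
            raise ValueError(f"pathway '{self.name}': seed and target overlap")
        if self.track_map.values.min() < 0 or self.track_map.values.max() > 1:
            raise ValueError(f"pathway '{self.name}': track map outside [0, 1]")


# ---------------------------------------------------------------------------
# Task GLM
# ---------------------------------------------------------------------------

def boxcar_design(n_volumes: int, block_volumes: int, n_cycles: int,
                  drift_order: int = 2) -> np.ndarray:
    """Design matrix [intercept, drift polynomials, boxcar] for an off/on block task.

    The boxcar starts in the off state: each cycle is ``block_volumes`` rest
    volumes followed by ``block_volumes`` task volumes. Volumes beyond the
    last cycle remain at rest. Drift regressors are Legendre polynomials on
    [-1, 1] up to ``drift_order`` (orthogonal to the intercept).
    """
    needed = 2 * block_volumes * n_cycles
    if n_volumes < needed:
        raise DesignError(
            f"series of {n_volumes} volumes too short for {n_cycles} off/on cycles "
            f"of {block_volumes} volumes each ({needed} needed)")
    boxcar = np.zeros(n_volumes)
    for c in range(n_cycles):
        start = (2 * c + 1) * block_volumes
        boxcar[start:start + block_volumes] = 1.0
    t = np.linspace(-1.0, 1.0, n_volumes)
    drift = [np.polynomial.legendre.Legendre.basis(k)(t) for k in range(1, drift_order + 1)]
    X = np.column_stack([np.ones(n_volumes), *drift, boxcar])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("rank-deficient design matrix")
    return X


def fit_boxcar_glm(series: TimeSeriesVolume, block_volumes: int, n_cycles: int,
                   drift_order: int = 2, task_label: str = "",
                   t_cap: float = 1e6) -> ActivationMap:
    """Voxel-wise OLS fit of a boxcar block design; returns the task-effect t map.

    t = boxcar coefficient / its standard error, with dof = n_volumes minus the
    number of regressors. Voxels fit exactly (zero residual) get ``±t_cap``.
    """
    X = boxcar_design(series.n_volumes, block_volumes, n_cycles, drift_order)
    n, p = X.shape
    dof = n - p
    if dof < 1:
        raise DesignError("no residual degrees of freedom")
    Y = series.values.reshape(-1, n).T  # (n, n_voxels)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    b = beta[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.sign(b) * t_cap)
    tmap = VoxelGrid(t.reshape(series.shape[:3]), series.affine, units="t")
    return ActivationMap(tmap=tmap, dof=dof, task_label=task_label)


# ---------------------------------------------------------------------------
# ROI constructors
# ---------------------------------------------------------------------------

def peak_voxel(amap: ActivationMap, search_mask: VoxelGrid) -> Tuple[int, int, int]:
    """Index of the maximum t within the mask; ties break to the
    lexicographically smallest (x, y, z)."""
    mask = np.asarray(search_mask.values) > 0
    if not mask.any():
        raise EmptyROIError("empty search mask")
    t = amap.tmap.values
    tmax = t[mask].max()
    # np.argwhere scans in C order, i.e. lexicographic (x, y, z)
    winners = np.argwhere(mask & (t == tmax))
    return tuple(int(c) for c in winners[0])


def sphere_roi(center_world_mm, radius_mm: float, grid: VoxelGrid,
               space: str = "anat", **roi_kwargs) -> SeedROI:
    """All voxels whose centers lie within ``radius_mm`` of a world-mm point."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center_world_mm, dtype=float)
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    inside = np.linalg.norm(world - center, axis=1) <= radius_mm
    if not inside.any():
        raise EmptyROIError(f"sphere at {center.tolist()} (r={radius_mm} mm) misses the grid")
    return SeedROI(frozenset(map(tuple, idx[inside].tolist())), space=space, **roi_kwargs)


def inplane_square_roi(center: Tuple[int, int, int], grid: VoxelGrid,
                       gm_mask: VoxelGrid, space: str = "rsfmri",
                       **roi_kwargs) -> SeedROI:
    """The 3x3 in-plane (axial, fixed z) neighbourhood of a voxel, within grey matter.

    An ROI clipped by the grid edge or the grey-matter mask keeps the surviving
    voxels and carries ``eroded=True``; the nominal seed is 9 voxels.
    """
    cx, cy, cz = (int(c) for c in center)
    if not grid.in_bounds((cx, cy, cz)):
        raise ValueError(f"center {center} outside grid {grid.shape}")
    gm = np.asarray(gm_mask.values) > 0
    if not gm[cx, cy, cz]:
        raise EmptyROIError(f"center {center} is outside the grey-matter mask")
    voxels = set()
    for dx, dy in itertools.product((-1, 0, 1), repeat=2):
        x, y = cx + dx, cy + dy
        if 0 <= x < grid.shape[0] and 0 <= y < grid.shape[1] and gm[x, y, cz]:
            voxels.add((x, y, cz))
    return SeedROI(frozenset(voxels), space=space, eroded=len(voxels) < 9, **roi_kwargs)


def max_corr_pair(series: TimeSeriesVolume, roi_a: SeedROI, roi_b: SeedROI,
                  gm_mask: VoxelGrid):
    """The voxel pair (a in roi_a, b in roi_b) with the highest Pearson correlation.

    Both ROIs are first restricted to grey matter; zero-variance voxel time
    courses are excluded. Expects the temporally filtered series. Ties break
    lexicographically on the (a, b) index pair.
    """
    gm = np.asarray(gm_mask.values) > 0

    def _masked_sorted(roi: SeedROI) -> np.ndarray:
        idx = roi.as_array()
        keep = gm[idx[:, 0], idx[:, 1], idx[:, 2]]
        out = idx[keep]
        if out.size == 0:
            raise EmptyROIError(
                f"ROI '{roi.pathway_name or roi.role}' empty after grey-matter masking")
        return out

    ia, ib = _masked_sorted(roi_a), _masked_sorted(roi_b)
    ta = series.values[ia[:, 0], ia[:, 1], ia[:, 2], :].astype(float)
    tb = series.values[ib[:, 0], ib[:, 1], ib[:, 2], :].astype(float)

    def _standardize(ts: np.ndarray):
        ts = ts - ts.mean(axis=1, keepdims=True)
        sd = ts.std(axis=1)
        ok = sd > 0
        ts[ok] /= sd[ok, None]
        return ts, ok

    za, oka = _standardize(ta)
    zb, okb = _standardize(tb)
    if not oka.any() or not okb.any():
        raise ValueError("all candidate voxels have zero-variance time courses")
    r = (za @ zb.T) / series.n_volumes
    r[~oka, :] = -np.inf
    r[:, ~okb] = -np.inf
    best = r.max()
    # first hit in C order of (a, b) = lexicographic tie-break, since ia/ib are sorted
    ai, bi = np.argwhere(r == best)[0]
    return tuple(int(c) for c in ia[ai]), tuple(int(c) for c in ib[bi])
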