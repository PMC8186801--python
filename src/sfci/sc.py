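"""Structural connectivity (sc): diffusion tensor fit, scalar maps, and the
track-probability-weighted pathway average.

sc is the pathway-averaged radial diffusivity (RD): the diffusion scalar of
interest D(v) averaged over voxels weighted by the track probability map
w(v) and restricted to the white-matter mask WM(v),

    <D> = sum_v D(v) · w(v) · WM(v) / sum_v w(v) · WM(v).

The normalizing denominator makes <D> a true weighted average, insensitive
to the overall scaling of the track map and comparable across subjects with
different tract sizes; the literal unnormalized sum is available behind
``normalized=False``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .volumes import TimeSeriesVolume, VoxelGrid

__all__ = [
    "TensorField",
    "ScalarMaps",
    "ScValue",
    "fit_tensor_loglinear",
    "tensor_scalars",
    "pathway_average",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TensorField:
    """Per-voxel diffusion tensor eigensystem.

    ``eigenvalues`` holds the sorted triple lambda1 >= lambda2 >= lambda3 in
    mm^2/s at each voxel. Negative eigenvalues (a noise artefact of the
    log-linear fit) are retained, not clipped — clipping would bias RD
    downward — and flagged in ``negative_eig``.
    """

    eigenvalues: np.ndarray  # (nx, ny, nz, 3), descending
    valid_mask: VoxelGrid
    affine: np.ndarray
    negative_eig: np.ndarray | None = None

    def __post_init__(self) -> None:
        ev = self.eigenvalues
        valid = np.asarray(self.valid_mask.values) > 0
        if not np.all(np.isfinite(ev[valid])):
            raise ValueError("non-finite eigenvalues inside the valid mask")
        if np.any(np.diff(ev[valid], axis=-1) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if self.negative_eig is None:
            neg = np.zeros(ev.shape[:3], dtype=bool)
            neg[valid] = (ev[valid] < 0).any(axis=-1)
            self.negative_eig = neg


@dataclasses.dataclass
class ScalarMaps:
    """FA (unitless) and AD/RD/MD diffusivities (mm^2/s)."""

    fa: VoxelGrid
    md: VoxelGrid
    ad: VoxelGrid
    rd: VoxelGrid
    valid_mask: VoxelGrid


@dataclasses.dataclass
class ScValue:
    value: float
    pathway_name: str
    subject: str = ""
    visit: int = 0
    normalized: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("sc must be finite")


_DESIGN_COLUMNS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def _tensor_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    cols = [np.ones(len(bvals))]
    for i, j in _DESIGN_COLUMNS:
        factor = 1.0 if i == j else 2.0
        cols.append(-bvals * factor * bvecs[:, i] * bvecs[:, j])
    return np.column_stack(cols)


def fit_tensor_loglinear(dwi: TimeSeriesVolume, bvals, bvecs,
                         mask: VoxelGrid | None = None) -> TensorField:
    """Standard log-linear least-squares diffusion tensor fit.

    Solves ln S = ln S0 - b g^T D g per voxel for the 6 unique tensor
    elements (plus ln S0) and eigendecomposes. Voxels with any non-positive
    signal are flagged invalid. Requires at least 7 volumes including one
    b = 0 acquisition.
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape == (3, len(bvals)):
        bvecs = bvecs.T
    if len(bvals) != dwi.n_volumes or bvecs.shape != (len(bvals), 3):
        raise ValueError("bvals/bvecs do not match the DWI volume count")
    if dwi.n_volumes < 7:
        raise ValueError("tensor fit needs >= 7 volumes")
    if not np.any(bvals == 0):
        raise ValueError("no b=0 volume in the acquisition")
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("diffusion-weighted bvecs must be unit vectors")

    shape = dwi.shape[:3]
    sel = np.ones(shape, bool) if mask is None else np.asarray(mask.values) > 0
    signals = dwi.values[sel].astype(float)  # (n_voxels, n_volumes)
    positive = (signals > 0).all(axis=1)

    X = _tensor_design(bvals, bvecs)
    pinv = np.linalg.pinv(X)
    coef = np.zeros((len(signals), 7))
    if positive.any():
        coef[positive] = (pinv @ np.log(signals[positive]).T).T

    D = np.zeros((len(signals), 3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = (coef[:, k] for k in range(1, 7))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = dxx, dyy, dzz
    D[:, 0, 1] = D[:, 1, 0] = dxy
    D[:, 0, 2] = D[:, 2, 0] = dxz
    D[:, 1, 2] = D[:, 2, 1] = dyz
    eig = np.linalg.eigvalsh(D)[:, ::-1]  # descending
    eig[~positive] = 0.0

    ev = np.zeros((*shape, 3))
    ev[sel] = eig
    valid = np.zeros(shape, dtype=np.uint8)
    valid[sel] = positive.astype(np.uint8)
    return TensorField(eigenvalues=ev,
                       valid_mask=VoxelGrid(valid, dwi.affine, "binary"),
                       affine=dwi.affine)


def tensor_scalars(field: TensorField) -> ScalarMaps:
    """AD = l1, RD = (l2+l3)/2, MD = mean(l), FA by the standard normalized
    eigenvalue-dispersion formula (0 where the tensor is all-zero)."""
    l1, l2, l3 = (field.eigenvalues[..., k] for k in range(3))
    ad = l1
    rd = (l2 + l3) / 2.0
    md = (l1 + l2 + l3) / 3.0
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    aff = field.affine
    return ScalarMaps(
        fa=VoxelGrid(fa, aff, units=""),
        md=VoxelGrid(md, aff, units="mm2/s"),
        ad=VoxelGrid(ad, aff, units="mm2/s"),
        rd=VoxelGrid(rd, aff, units="mm2/s"),
        valid_mask=field.valid_mask,
    )


def pathway_average(d_map: VoxelGrid, track_map: VoxelGrid, wm_mask: VoxelGrid,
                    normalized: bool = True, pathway_name: str = "",
                    subject: str = "", visit: int = 0) -> ScValue:
    """Track-probability- and white-matter-weighted pathway mean of a scalar map.

    ``track_map`` may be a probability field in [0, 1] or raw visitation
    counts; count-dialect maps (max > 1) are rescaled by their maximum, with
    a log notice. With ``normalized=False`` the literal weighted sum is
    returned instead of the weighted mean.
    """
    if not (d_map.shape == track_map.shape == wm_mask.shape):
        raise ValueError("scalar map, track map, and WM mask must share a shape")
    w = np.asarray(track_map.values, dtype=float)
    if w.min() < 0:
        raise ValueError("track map has negative weights")
    if w.max() > 1:
        logger.info("track map '%s' looks like visitation counts (max=%g); rescaling by max",
                    pathway_name, w.max())
        w = w / w.max()
    wm = (np.asarray(wm_mask.values) > 0).astype(float)
    weights = w * wm
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"pathway '{pathway_name}': zero total weight under the WM mask")
    s = float((np.asarray(d_map.values, dtype=float) * weights).sum())
    value = s / total if normalized else s
    return ScValue(value=value, pathway_name=pathway_name, subject=subject,
                   visit=visit, normalized=normalized)
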