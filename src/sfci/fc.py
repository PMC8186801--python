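"""Seed-based resting-state functional connectivity (fc).

The pipeline, in run order:

1. 2-D in-plane Hamming apodization of each axial slice (spatial smoothing
   with minimal resolution loss), then zero-phase temporal low-pass at
   0.08 Hz.
2. Reference time series = linearly detrended mean of the seed voxels.
3. Whole-brain Pearson correlation map against the reference; conversion to
   Student's t; whole-brain z-normalization (in-mask mean 0, SD 1) to absorb
   individual differences in global signal.
4. fc = mean z over the 9-voxel target seed.

The z-normalization makes the final fc invariant to any affine rescaling of
the t map, so the choice of effective sample size in the r-to-t step only
enters through a monotone map.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volumes import SeedROI, TimeSeriesVolume, VoxelGrid

__all__ = [
    "ReferenceTimeSeries",
    "ConnectivityMap",
    "FcValue",
    "lowpass_filter",
    "inplane_hamming_filter",
    "inplane_gaussian_filter",
    "seed_reference",
    "correlation_map",
    "r_to_t",
    "normalize_t_to_z",
    "extract_fc",
    "compute_fc",
]


@dataclasses.dataclass
class ReferenceTimeSeries:
    values: np.ndarray
    source_roi: SeedROI
    detrended: bool = True


@dataclasses.dataclass
class ConnectivityMap:
    """A whole-brain connectivity map at one of the stages r, t, or z.

    ``mask`` is the brain mask the map was computed (and, at stage z,
    normalized) within; ``invalid`` flags zero-variance voxels whose r was
    recorded as 0.
    """

    grid: VoxelGrid
    stage: str
    dof: int
    mask: VoxelGrid | None = None
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("r", "t", "z"):
            raise ValueError(f"unknown stage '{self.stage}'")
        if self.stage == "r":
            v = self.grid.values
            sel = np.ones(v.shape, bool) if self.mask is None else self.mask.values > 0
            if np.nanmax(np.abs(v[sel])) > 1 + 1e-12:
                raise ValueError("r-stage map has values outside [-1, 1]")


@dataclasses.dataclass
class FcValue:
    value: float
    pathway_name: str
    subject: str = ""
    visit: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("fc must be finite")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def lowpass_filter(series: TimeSeriesVolume, cutoff_hz: float = 0.08,
                   transition: float = 0.15) -> TimeSeriesVolume:
    """Zero-phase temporal low-pass removing fluctuations above ``cutoff_hz``.

    Realized as a frequency-domain mask with a raised-cosine rolloff from
    (1 - transition)·cutoff to (1 + transition)·cutoff: unit gain in the
    passband (DC preserved exactly), zero beyond the transition band, no
    phase distortion of the correlations computed downstream.
    """
    nyquist = 1.0 / (2.0 * series.tr_s)
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.4g} Hz)")
    n = series.n_volumes
    freqs = np.fft.rfftfreq(n, d=series.tr_s)
    f_lo = (1.0 - transition) * cutoff_hz
    f_hi = (1.0 + transition) * cutoff_hz
    gain = np.ones_like(freqs)
    band = (freqs > f_lo) & (freqs < f_hi)
    gain[band] = 0.5 * (1.0 + np.cos(np.pi * (freqs[band] - f_lo) / (f_hi - f_lo)))
    gain[freqs >= f_hi] = 0.0
    spec = np.fft.rfft(series.values, axis=-1)
    out = np.fft.irfft(spec * gain, n=n, axis=-1)
    return TimeSeriesVolume(out, series.affine, tr_s=series.tr_s)


def _freq_hamming(n: int) -> np.ndarray:
    """Hamming taper over spatial frequency, 1 at DC, 0.08 at Nyquist."""
    k = np.abs(np.fft.fftfreq(n))  # cycles/voxel in [0, 0.5]
    return 0.54 + 0.46 * np.cos(np.pi * k / 0.5)


def inplane_hamming_filter(series: TimeSeriesVolume) -> TimeSeriesVolume:
    """2-D in-plane Hamming apodization of each axial slice's spatial spectrum.

    The window is separable in (kx, ky), equals 1 at DC (slice means are
    preserved) and 0.08 at the in-plane Nyquist frequency.
    """
    nx, ny = series.shape[:2]
    if nx < 4 or ny < 4:
        raise ValueError("in-plane dimensions must be >= 4")
    window = np.outer(_freq_hamming(nx), _freq_hamming(ny))
    spec = np.fft.fft2(series.values, axes=(0, 1))
    out = np.fft.ifft2(spec * window[:, :, None, None], axes=(0, 1)).real
    return TimeSeriesVolume(out, series.affine, tr_s=series.tr_s)


def inplane_gaussian_filter(series: TimeSeriesVolume, fwhm_mm: float = 4.0) -> TimeSeriesVolume:
    """Separable 2-D in-plane Gaussian smoothing (task-fMRI branch only)."""
    voxel = np.linalg.norm(series.affine[:3, :3], axis=0)[:2]
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxel
    out = ndimage.gaussian_filter(series.values, sigma=(*sigma_vox, 0, 0), mode="nearest")
    return TimeSeriesVolume(out, series.affine, tr_s=series.tr_s)


# ---------------------------------------------------------------------------
# Correlation pipeline
# ---------------------------------------------------------------------------

def seed_reference(series: TimeSeriesVolume, seed: SeedROI) -> ReferenceTimeSeries:
    """Linearly detrended arithmetic average of the seed voxels' time courses."""
    idx = seed.as_array()
    for v in idx:
        if not all(0 <= v[d] < series.shape[d] for d in range(3)):
            raise ValueError(f"seed voxel {tuple(v)} outside series grid {series.shape[:3]}")
    mean_ts = series.values[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)
    t = np.arange(series.n_volumes, dtype=float)
    slope, intercept = np.polyfit(t, mean_ts, 1)
    detrended = mean_ts - (slope * t + intercept)
    return ReferenceTimeSeries(values=detrended, source_roi=seed, detrended=True)


def correlation_map(series: TimeSeriesVolume, ref: ReferenceTimeSeries,
                    brain_mask: VoxelGrid) -> ConnectivityMap:
    """Pearson r between the reference and every in-mask voxel time course.

    Out-of-mask voxels are 0; in-mask voxels with zero temporal variance get
    r = 0 and are flagged in ``invalid``.
    """
    refv = np.asarray(ref.values, dtype=float)
    if len(refv) != series.n_volumes:
        raise ValueError("reference length does not match the series")
    refc = refv - refv.mean()
    ref_sd = refc.std()
    if ref_sd == 0:
        raise ValueError("zero-variance reference time series")
    mask = np.asarray(brain_mask.values) > 0
    if not mask.any():
        raise ValueError("empty brain mask")
    data = series.values[mask].astype(float)  # (n_in_mask, t)
    data = data - data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1)
    ok = sd > 0
    r_vals = np.zeros(len(data))
    r_vals[ok] = (data[ok] @ refc) / (series.n_volumes * sd[ok] * ref_sd)
    np.clip(r_vals, -1.0, 1.0, out=r_vals)
    rmap = np.zeros(series.shape[:3])
    rmap[mask] = r_vals
    invalid = np.zeros(series.shape[:3], dtype=bool)
    invalid[mask] = ~ok
    grid = VoxelGrid(rmap, series.affine, units="r")
    return ConnectivityMap(grid=grid, stage="r", dof=series.n_volumes - 2,
                           mask=VoxelGrid(mask.astype(np.uint8), series.affine, "binary"),
                           invalid=invalid)


def r_to_t(cmap: ConnectivityMap, n_effective: int, t_cap: float = 1e6) -> ConnectivityMap:
    """t(v) = r(v)·sqrt((n_eff - 2) / (1 - r(v)^2)); |r| = 1 maps to ±t_cap.

    ``n_effective`` defaults in practice to the nominal number of volumes;
    low-pass filtering reduces the true temporal dof, but the subsequent
    whole-brain z-normalization removes global scale, so the choice cannot
    change fc by more than a monotone map.
    """
    if cmap.stage != "r":
        raise ValueError("r_to_t expects an r-stage map")
    if n_effective < 3:
        raise ValueError("n_effective must be >= 3")
    r = cmap.grid.values
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_effective - 2) / (1.0 - r ** 2))
    t = np.where(np.abs(r) >= 1.0, np.sign(r) * t_cap, t)
    np.clip(t, -t_cap, t_cap, out=t)
    grid = VoxelGrid(t, cmap.grid.affine, units="t")
    return ConnectivityMap(grid=grid, stage="t", dof=n_effective - 2,
                           mask=cmap.mask, invalid=cmap.invalid)


def normalize_t_to_z(cmap: ConnectivityMap, brain_mask: VoxelGrid | None = None,
                     ddof: int = 0) -> ConnectivityMap:
    """Normalize the whole-brain (in-mask) t distribution to mean 0, SD 1.

    Uses the population SD convention (``ddof=0``) by default; the convention
    cancels in any within-study contrast as long as it is fixed.
    """
    if cmap.stage != "t":
        raise ValueError("normalize_t_to_z expects a t-stage map")
    mask_grid = brain_mask if brain_mask is not None else cmap.mask
    if mask_grid is None:
        raise ValueError("a brain mask is required")
    mask = np.asarray(mask_grid.values) > 0
    vals = cmap.grid.values[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    mu, sd = vals.mean(), vals.std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate t map: zero in-mask variance")
    z = np.zeros_like(cmap.grid.values)
    z[mask] = (vals - mu) / sd
    grid = VoxelGrid(z, cmap.grid.affine, units="z")
    return ConnectivityMap(grid=grid, stage="z", dof=cmap.dof,
                           mask=VoxelGrid(mask.astype(np.uint8), cmap.grid.affine, "binary"),
                           invalid=cmap.invalid)


def extract_fc(zmap: ConnectivityMap, target: SeedROI, subject: str = "",
               visit: int = 0) -> FcValue:
    """fc = arithmetic mean of the normalized z over the target seed voxels."""
    if zmap.stage != "z":
        raise ValueError("extract_fc expects a z-stage map")
    idx = target.as_array()
    mask = np.asarray(zmap.mask.values) > 0 if zmap.mask is not None else None
    if mask is not None:
        inside = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        if not inside.all():
            raise ValueError(
                f"{int((~inside).sum())} target voxel(s) fall outside the normalized mask")
    value = float(zmap.grid.values[idx[:, 0], idx[:, 1], idx[:, 2]].mean())
    return FcValue(value=value, pathway_name=target.pathway_name,
                   subject=subject, visit=visit)


def compute_fc(series: TimeSeriesVolume, seed: SeedROI, target: SeedROI,
               brain_mask: VoxelGrid, cutoff_hz: float = 0.08,
               n_effective: int | None = None, t_cap: float = 1e6,
               spatial_filter: bool = True, subject: str = "",
               visit: int = 0) -> FcValue:
    """Full seed-to-target fc pipeline on a (preprocessed) resting-state series."""
    if spatial_filter:
        series = inplane_hamming_filter(series)
    series = lowpass_filter(series, cutoff_hz=cutoff_hz)
    ref = seed_reference(series, seed)
    rmap = correlation_map(series, ref, brain_mask)
    tmap = r_to_t(rmap, n_effective or series.n_volumes, t_cap=t_cap)
    zmap = normalize_t_to_z(tmap)
    return extract_fc(zmap, target, subject=subject, visit=visit)
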