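"""Synthetic data: longitudinal progression cohorts and volumetric test fixtures.

Two tiers, both fully deterministic under a seed:

* **Measure-level cohorts** — the composite metric was originally developed
  on generated longitudinal data before being applied to a real sample.
  :func:`simulate_cohort` draws per-subject baselines and per-group decline
  slopes for fc and sc on each pathway, and the ROC machinery
  (:func:`detect_progression`, :func:`roc_auc`, :func:`auc_vs_timepoints`)
  evaluates how well slope-based scores separate progressors from stable
  subjects as a function of the number of time points. The exact generative
  parameters and the definitions of the three candidate measures are a
  reconstruction: M1 is the full combined index, M2 the fc-only composite,
  M3 the sc-only composite.

* **Volume-level fixtures** — :func:`make_image_fixtures` emits a small,
  geometrically consistent set of volumes (a resting series with a planted
  seed-target correlation, a task series with a planted activation peak, a
  diffusivity map with a weighted tract, masks) so the imaging pipeline can
  be exercised end-to-end with no acquired data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metric
from .metric import COG_LEFT, COG_RIGHT, MOTOR_PATHWAY, PATHWAYS, NormativeStats
from .volumes import SeedROI, TimeSeriesVolume, VoxelGrid, write_volume

__all__ = [
    "SimulationConfig",
    "ROCCurve",
    "MeasureDefinition",
    "MEASURES",
    "simulate_cohort",
    "detect_progression",
    "roc_auc",
    "auc_vs_timepoints",
    "ImageFixtures",
    "make_image_fixtures",
]

COGNITIVE_PATHWAYS = (COG_LEFT, COG_RIGHT)


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters for a longitudinal two-group cohort.

    Defaults mirror the study conditions: 20 progressors vs 9 stable
    subjects, up to nine equally spaced time points. fc is in normalized z
    units (a connected pathway sits well above the whole-brain mean); sc is
    radial diffusivity in mm^2/s, rising with white-matter damage. Slopes
    are per-subject normal draws (units per visit); measurement noise is
    visit-level and independent.
    """

    n_progressors: int = 20
    n_stable: int = 9
    n_timepoints: int = 9
    fc_baseline_mean: float = 1.5
    fc_baseline_sd: float = 0.4
    sc_baseline_mean: float = 0.5e-3
    sc_baseline_sd: float = 0.05e-3
    fc_slope_mean: float = -0.05      # progressor decline, z units / visit
    fc_slope_sd: float = 0.02
    sc_slope_mean: float = 0.01e-3    # progressor RD rise, mm^2/s / visit
    sc_slope_sd: float = 0.004e-3
    stable_slope_sd_fc: float = 0.01  # stable group: zero-mean slope jitter
    stable_slope_sd_sc: float = 0.002e-3
    fc_noise_sd: float = 0.15
    sc_noise_sd: float = 0.015e-3
    scenario: str = "uniform_decline"  # or "domain_specific"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progressors < 1 or self.n_stable < 1:
            raise ValueError("both groups need at least one subject")
        if not 1 <= self.n_timepoints <= 9:
            raise ValueError("n_timepoints must be in 1..9")
        if self.scenario not in ("uniform_decline", "domain_specific"):
            raise ValueError(f"unknown scenario '{self.scenario}'")
        for name in ("fc_baseline_sd", "sc_baseline_sd", "fc_slope_sd", "sc_slope_sd",
                     "stable_slope_sd_fc", "stable_slope_sd_sc",
                     "fc_noise_sd", "sc_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def declining_pathways(self) -> Tuple[str, ...]:
        """Pathways whose progressor slopes are non-zero under this scenario."""
        if self.scenario == "uniform_decline":
            return PATHWAYS
        return COGNITIVE_PATHWAYS  # domain_specific: cognitive domain only


def simulate_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw a longitudinal cohort of pathway measures.

    value(visit) = baseline + slope * visit + noise, with baselines and
    slopes per subject x pathway x component and visits indexed 0..T-1.
    Returns the tidy frame (subject, group, visit, pathway, fc, sc).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    declining = np.array([p in cfg.declining_pathways() for p in PATHWAYS])
    T = cfg.n_timepoints
    visits = np.arange(T, dtype=float)
    frames = []
    groups = [("P", "progressor", cfg.n_progressors), ("S", "stable", cfg.n_stable)]
    for prefix, group, n_sub in groups:
        npath = len(PATHWAYS)
        fc0 = rng.normal(cfg.fc_baseline_mean, cfg.fc_baseline_sd, (n_sub, npath))
        sc0 = rng.normal(cfg.sc_baseline_mean, cfg.sc_baseline_sd, (n_sub, npath))
        if group == "progressor":
            fc_slope = np.where(
                declining,
                rng.normal(cfg.fc_slope_mean, cfg.fc_slope_sd, (n_sub, npath)),
                rng.normal(0.0, cfg.stable_slope_sd_fc, (n_sub, npath)))
            sc_slope = np.where(
                declining,
                rng.normal(cfg.sc_slope_mean, cfg.sc_slope_sd, (n_sub, npath)),
                rng.normal(0.0, cfg.stable_slope_sd_sc, (n_sub, npath)))
        else:
            fc_slope = rng.normal(0.0, cfg.stable_slope_sd_fc, (n_sub, npath))
            sc_slope = rng.normal(0.0, cfg.stable_slope_sd_sc, (n_sub, npath))
        fc = (fc0[..., None] + fc_slope[..., None] * visits
              + rng.normal(0, cfg.fc_noise_sd, (n_sub, npath, T)))
        sc = (sc0[..., None] + sc_slope[..., None] * visits
              + rng.normal(0, cfg.sc_noise_sd, (n_sub, npath, T)))
        subjects = np.array([f"{prefix}{s:03d}" for s in range(n_sub)])
        frames.append(pd.DataFrame({
            "subject": np.repeat(subjects, npath * T),
            "group": group,
            "visit": np.tile(np.arange(T), n_sub * npath),
            "pathway": np.tile(np.repeat(PATHWAYS, T), n_sub),
            "fc": fc.ravel(),
            "sc": sc.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Candidate measures and progression detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MeasureDefinition:
    """A candidate composite: maps per-pathway component z-scores to a scalar.

    The combiner receives oriented fc and sc z-scores keyed by pathway and
    must be deterministic.
    """

    name: str
    combiner: Callable[[Dict[str, float], Dict[str, float]], float]


def _combine(z_by_pathway: Dict[str, float]):
    # np.minimum so combiners work elementwise on arrays as well as scalars
    return 0.5 * z_by_pathway[MOTOR_PATHWAY] + 0.5 * np.minimum(
        z_by_pathway[COG_LEFT], z_by_pathway[COG_RIGHT])


def _m1(zfc: Dict[str, float], zsc: Dict[str, float]) -> float:
    return _combine({p: 0.5 * (zfc[p] + zsc[p]) for p in PATHWAYS})


def _m2(zfc: Dict[str, float], zsc: Dict[str, float]) -> float:
    return _combine(dict(zfc))


def _m3(zfc: Dict[str, float], zsc: Dict[str, float]) -> float:
    return _combine(dict(zsc))


MEASURES: Dict[str, MeasureDefinition] = {
    "M1_combined": MeasureDefinition("M1_combined", _m1),
    "M2_fc_only": MeasureDefinition("M2_fc_only", _m2),
    "M3_sc_only": MeasureDefinition("M3_sc_only", _m3),
}


def _component_z(measures: pd.DataFrame, norms: NormativeStats
                 ) -> pd.DataFrame:
    """Oriented per-record fc and sc z-scores against the norms."""
    df = measures.copy()
    s_fc, s_sc = norms.signs
    t = norms.table
    fc_mean = df["pathway"].map(t["fc_mean"])
    fc_sd = df["pathway"].map(t["fc_sd"])
    sc_mean = df["pathway"].map(t["sc_mean"])
    sc_sd = df["pathway"].map(t["sc_sd"])
    df["z_fc"] = s_fc * (df["fc"] - fc_mean) / fc_sd
    df["z_sc"] = s_sc * (df["sc"] - sc_mean) / sc_sd
    return df


def detect_progression(measures: pd.DataFrame, measure_def: MeasureDefinition,
                       n_timepoints: int,
                       norms: NormativeStats | None = None) -> pd.DataFrame:
    """Per-subject progression score from the candidate measure's decline.

    The candidate measure is evaluated at each of the first ``n_timepoints``
    visits and its per-subject ordinary-least-squares slope is computed; the
    score is the *negative* slope, so faster decline scores higher. Norms
    default to the stable group's baseline visit.

    Returns a frame (subject, group, score).
    """
    if n_timepoints < 2:
        raise ValueError("slope-based detection needs >= 2 time points")
    df = measures[measures["visit"] < n_timepoints]
    if df["visit"].nunique() < n_timepoints:
        raise ValueError(f"cohort has fewer than {n_timepoints} visits")
    if norms is None:
        base = df[(df["group"] == "stable") & (df["visit"] == 0)]
        norms = metric.compute_norms(base, source="simulated stable baseline")
    z = _component_z(df, norms)
    wide = z.pivot(index=["subject", "group", "visit"], columns="pathway",
                   values=["z_fc", "z_sc"]).sort_index()
    if wide.isna().any().any():
        raise ValueError("every subject-visit needs all three pathways")
    zfc = {p: wide[("z_fc", p)].to_numpy() for p in PATHWAYS}
    zsc = {p: wide[("z_sc", p)].to_numpy() for p in PATHWAYS}
    values = np.asarray(measure_def.combiner(zfc, zsc), dtype=float)
    # balanced design: every subject carries visits 0..t-1, so the OLS slope
    # reduces to a closed form on the (n_subjects, t) value matrix
    index = wide.index.droplevel("visit").unique()
    mat = values.reshape(len(index), n_timepoints)
    t = np.arange(n_timepoints, dtype=float)
    tc = t - t.mean()
    slopes = (mat - mat.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    return pd.DataFrame({"subject": index.get_level_values("subject"),
                         "group": index.get_level_values("group"),
                         "score": -slopes})


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC over all score thresholds; higher score = positive call.

    The AUC equals the Mann-Whitney U statistic over positive/negative pairs
    divided by n1*n0, with tied scores contributing 1/2 — the probability
    that a random positive outscores a random negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if not set(np.unique(labels)) == {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    pos, neg = scores[labels == 1], scores[labels == 0]
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(pos >= th).mean() for th in thresholds])
    spec = np.array([(neg < th).mean() for th in thresholds])
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (len(pos) * len(neg))
    return ROCCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=float(auc))


def auc_vs_timepoints(cfg: SimulationConfig,
                      measure_defs: Iterable[MeasureDefinition] | None = None,
                      max_timepoints: int | None = None,
                      n_replicates: int = 200,
                      ci: Tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Mean AUC (with a percentile CI over replicates) per measure and design length.

    For each replicate a fresh cohort is simulated from ``cfg`` (seeds derived
    deterministically from ``cfg.rng_seed``) and each candidate measure is
    scored at every number of time points t = 2..max_timepoints.
    """
    measure_defs = list(measure_defs) if measure_defs is not None else list(MEASURES.values())
    max_timepoints = max_timepoints or cfg.n_timepoints
    if max_timepoints > cfg.n_timepoints:
        raise ValueError("max_timepoints exceeds the simulated visit count")
    seeds = np.random.SeedSequence(cfg.rng_seed).generate_state(n_replicates)
    aucs: Dict[Tuple[str, int], List[float]] = {}
    for seed in seeds:
        rep_cfg = dataclasses.replace(cfg, rng_seed=int(seed % (2 ** 31)))
        cohort = simulate_cohort(rep_cfg)
        base = cohort[(cohort["group"] == "stable") & (cohort["visit"] == 0)]
        norms = metric.compute_norms(base, source="simulated stable baseline")
        for t in range(2, max_timepoints + 1):
            for mdef in measure_defs:
                scored = detect_progression(cohort, mdef, t, norms=norms)
                labels = (scored["group"] == "progressor").astype(int)
                curve = roc_auc(scored["score"].to_numpy(), labels.to_numpy())
                aucs.setdefault((mdef.name, t), []).append(curve.auc)
    rows = []
    for (name, t), vals in sorted(aucs.items()):
        arr = np.asarray(vals)
        lo, hi = np.percentile(arr, ci)
        rows.append({"measure": name, "n_timepoints": t, "mean_auc": arr.mean(),
                     "ci_low": lo, "ci_high": hi, "n_replicates": len(arr)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Volume-level fixtures
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ImageFixtures:
    """A geometrically consistent set of synthetic volumes with ground truth."""

    rest_series: TimeSeriesVolume
    task_series: TimeSeriesVolume
    rd_map: VoxelGrid
    track_map: VoxelGrid
    brain_mask: VoxelGrid
    gm_mask: VoxelGrid
    wm_mask: VoxelGrid
    seed: SeedROI
    target: SeedROI
    manifest: Dict[str, object]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(self.rest_series, out / "rest.nii.gz")
        write_volume(self.task_series, out / "task.nii.gz")
        for name in ("rd_map", "track_map", "brain_mask", "gm_mask", "wm_mask"):
            write_volume(getattr(self, name), out / f"{name}.nii.gz")
        write_volume(self.seed.to_mask(self.brain_mask), out / "seed_mask.nii.gz")
        write_volume(self.target.to_mask(self.brain_mask), out / "target_mask.nii.gz")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _bandlimited_noise(rng: np.random.Generator, n: int, tr_s: float,
                       max_hz: float, size=()) -> np.ndarray:
    """Standardized Gaussian noise with power only below ``max_hz`` (so the
    planted signal survives the pipeline's temporal low-pass)."""
    white = rng.standard_normal((*size, n))
    freqs = np.fft.rfftfreq(n, d=tr_s)
    spec = np.fft.rfft(white, axis=-1)
    spec[..., freqs > max_hz] = 0.0
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def _square(center: Tuple[int, int, int], **kwargs) -> SeedROI:
    cx, cy, cz = center
    vox = {(cx + dx, cy + dy, cz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)}
    return SeedROI(frozenset(vox), **kwargs)


def make_image_fixtures(shape: Tuple[int, int, int] = (24, 24, 12),
                        n_volumes: int = 60, tr_s: float = 2.8,
                        rho: float = 0.9, noise_sd: float = 1.0,
                        task_amplitude: float = 5.0,
                        tract_rd: float = 0.6e-3,
                        background_rd: float = 0.4e-3,
                        rng_seed: int = 0,
                        out_dir=None) -> ImageFixtures:
    """Build the synthetic volume set for exercising the imaging pipeline.

    The resting series carries a low-frequency latent signal in a 9-voxel
    seed and, at correlation ``rho``, in a 9-voxel target, on top of white
    noise. The task series plants a noiseless-boxcar-plus-noise activation
    at a known voxel (4 cycles of 8 off / 8 on volumes). The diffusivity map
    holds ``tract_rd`` along a straight seed-to-target tract covered by a
    smooth track probability map. The manifest records all planted truths.
    """
    nx, ny, nz = shape
    if min(nx, ny) < 12 or nz < 4:
        raise ValueError(f"fixture shape {shape} too small for the planted geometry")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    affine = np.diag([2.0, 2.0, 4.0, 1.0])
    zmid = nz // 2
    seed_center = (nx // 4, ny // 2, zmid)
    target_center = (3 * nx // 4, ny // 2, zmid)
    peak_voxel = (nx // 2, ny // 4, zmid)

    seed = _square(seed_center, space="rsfmri", role="seed", pathway_name="planted")
    target = _square(target_center, space="rsfmri", role="target", pathway_name="planted")

    # masks: brain = everything, GM = top/bottom shell + seed slabs, WM = interior
    brain = np.ones(shape, dtype=np.uint8)
    wm = np.zeros(shape, dtype=np.uint8)
    wm[2:-2, 2:-2, 1:-1] = 1
    gm = np.ones(shape, dtype=np.uint8)  # permissive GM so seeds never erode here

    # resting series: white noise + band-limited latent signal in seed/target
    latent = _bandlimited_noise(rng, n_volumes, tr_s, max_hz=0.06)
    rest = rng.normal(0.0, noise_sd, size=(*shape, n_volumes))
    for (x, y, z) in sorted(seed.voxel_indices):
        rest[x, y, z, :] += 2.0 * latent
    for (x, y, z) in sorted(target.voxel_indices):
        independent = _bandlimited_noise(rng, n_volumes, tr_s, max_hz=0.06)
        rest[x, y, z, :] += 2.0 * (rho * latent + np.sqrt(1.0 - rho ** 2) * independent)
    rest_series = TimeSeriesVolume(rest, affine, tr_s=tr_s)

    # task series: boxcar activation at the known peak
    n_task = 64
    boxcar = np.zeros(n_task)
    for c in range(4):
        boxcar[(2 * c + 1) * 8:(2 * c + 2) * 8] = 1.0
    task = rng.normal(0.0, noise_sd, size=(*shape, n_task))
    task[peak_voxel] += task_amplitude * boxcar
    task_series = TimeSeriesVolume(task, affine, tr_s=tr_s)

    # tract: straight line seed->target, dilated in-plane; RD elevated on it
    tract = np.zeros(shape, dtype=bool)
    x0, x1 = seed_center[0], target_center[0]
    for x in range(min(x0, x1), max(x0, x1) + 1):
        tract[x, ny // 2 - 1:ny // 2 + 2, zmid - 1:zmid + 2] = True
    rd = np.full(shape, background_rd)
    rd[tract] = tract_rd
    from scipy import ndimage
    # smooth within the tract but zero outside it, so the map's support stays
    # inside the constant-RD region
    track = ndimage.gaussian_filter(tract.astype(float), sigma=1.0) * tract
    track /= track.max()

    manifest = {
        "rho": rho, "seed_center": seed_center, "target_center": target_center,
        "activation_peak": peak_voxel, "tract_rd": tract_rd,
        "background_rd": background_rd, "tr_s": tr_s,
        "task_block_volumes": 8, "task_n_cycles": 4,
        "rng_seed": rng_seed, "shape": shape, "n_volumes": n_volumes,
    }
    fixtures = ImageFixtures(
        rest_series=rest_series, task_series=task_series,
        rd_map=VoxelGrid(rd, affine, units="mm2/s"),
        track_map=VoxelGrid(track, affine, units="probability"),
        brain_mask=VoxelGrid(brain, affine, units="binary"),
        gm_mask=VoxelGrid(gm, affine, units="binary"),
        wm_mask=VoxelGrid(wm, affine, units="binary"),
        seed=seed, target=target, manifest=manifest,
    )
    if out_dir is not None:
        fixtures.write(out_dir)
    return fixtures
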