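# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## The composite index

The package computes a single z-scored index of pathway connectivity for a
subject at a visit. Three white-matter pathways contribute: the
transcallosal sensorimotor (SMC) pathway for the motor domain and the left
and right posterior cingulum bundles (PCC–AMTL) for the cognitive domain.
Each pathway yields two measurements:

* **fc** — seed-based resting-state functional connectivity: the mean value
  over a 9-voxel target seed in a whole-brain correlation map that has been
  converted to Student's t and normalized to in-mask mean 0 / SD 1
  ("z units"). The whole-brain normalization absorbs individual differences
  in global signal amplitude.
* **sc** — structural connectivity: radial diffusivity (RD, mm²/s) averaged
  over the pathway with weights given by a track probability map restricted
  to white matter. RD rises with demyelination and axonal loss.

Against a normative sample with per-pathway means and SDs, each pathway's
component score is

    Z = ½ [ s_fc (fc − fc_pop)/σ_fc + s_sc (sc − sc_pop)/σ_sc ]

and the composite is

    SFCI = ½ Z_motor + ½ min(Z_cog_L, Z_cog_R),

the minimum making the cognitive term sensitive to impairment in either
hemisphere.

**Orientation signs.** The default is s_fc = +1, s_sc = −1. fc falls with
impairment while sc (RD) rises, so negating the structural z makes both
components decline with worsening disease; this matches the observed
directionality of the index (lower in patients, positively correlated with
behavioural performance, negatively with RD). An equal-signs "literal" mode
(both +1) is available via `orientation="literal"` / `--literal-eq1` for
sensitivity analysis; the two modes agree exactly whenever sc equals the
normative mean.

**Norming.** The normative statistics use the sample mean and SD (N−1
denominator) per pathway, computed from whatever rows the caller supplies —
typically healthy-control baseline visits, but the index can equally be
normed to a patient sample. Norming requires at least two subjects and
positive SDs; by construction, scoring the norming sample itself yields
component z-scores with mean 0 and SD 1.

**Missing data.** A subject-visit missing any pathway — including a single
cognitive hemisphere — is skipped and reported, never imputed: a minimum
over one value would silently change the estimand.

## Functional connectivity pipeline

Order of operations, on a preprocessed (motion- and physiology-corrected)
4-D series: 2-D in-plane spatial filtering → temporal low-pass → seed
reference → correlation → t conversion → whole-brain z-normalization →
target averaging.

* **In-plane Hamming filter.** Each axial slice's 2-D spatial spectrum is
  apodized with a separable Hamming taper, 1 at DC (slice means exactly
  preserved) and 0.08 at the in-plane Nyquist frequency.
* **Temporal low-pass at 0.08 Hz.** A zero-phase frequency-domain mask with
  a raised-cosine rolloff over ±15% of the cutoff: unit passband gain, zero
  beyond the transition band, no phase distortion of downstream
  correlations. The cutoff must lie below the Nyquist frequency 1/(2·TR).
* **Seed reference.** The arithmetic mean of the seed voxels' time courses,
  linearly detrended by least squares.
* **Correlation and t conversion.** Pearson r per in-mask voxel, then
  t = r·√((n_eff − 2)/(1 − r²)). |r| = 1 maps to ±t_cap (default 10⁶). The
  nominal volume count is used for n_eff by default; temporal filtering
  reduces the true effective dof, but because the next step removes global
  scale, the choice affects fc only through a monotone map, and a
  caller-supplied n_eff is accepted.
* **z-normalization.** (t − mean)/SD over the brain mask, population-SD
  convention (divide by N). The convention is arbitrary but must be fixed;
  it cancels in any within-study contrast.
* **fc extraction.** Mean z over the target seed; every target voxel must
  lie inside the normalized mask.

The task-fMRI branch (seed definition only) instead uses a separable
in-plane Gaussian of 4 mm FWHM before the block-design GLM.

For the cognitive pathway the implementation uses a per-hemisphere reading:
one 9-voxel PCC seed yields one map, and fc is read at the ipsilateral AMTL
seed. (A bilateral-reference mode can be assembled by passing a combined
seed ROI, but it is not the default.)

## Seed definition

* **Motor seeds** come from a block-design GLM on the tapping task: OLS per
  voxel on [intercept, Legendre drift up to order 2, boxcar], t = boxcar
  coefficient / SE. The drift basis and order are configurable; order 2 is
  a conventional default for runs of a few minutes. The peak voxel is the
  maximum t within a caller-supplied search mask (no atlas dependency), and
  the seed is the 3×3 in-plane neighbourhood of the peak.
* **Cognitive seeds** start from a 6 mm sphere at the PCC's literature
  coordinate in world mm (for reference, [−12, −42, 36] in the atlas space
  the coordinate was reported in) plus a manually drawn AMTL mask, then the
  maximally correlated PCC/AMTL voxel pair in the filtered resting series
  defines the centers of the 9-voxel functional seeds.
* **Erosion.** Manual removal of seed voxels falling in intragyral CSF is
  replaced by deterministic intersection with the supplied grey-matter
  mask; ROIs that lose voxels carry an `eroded` flag. Reproducibility
  requires removing the human-in-the-loop step.
* **Tie-breaks** (peak voxel, correlation pair) are lexicographic on voxel
  index, so results are identical across platforms.
* **ROI transfer** between co-registered spaces maps voxel centers through
  the world-coordinate affine chain and assigns nearest-neighbour
  destination voxels; indices are 0-based throughout and world coordinates
  follow the NIfTI affine convention.

## Structural connectivity

The diffusion tensor is fit per voxel by log-linear least squares —
ln S = ln S₀ − b gᵀDg solved for the six unique tensor elements plus
ln S₀ — requiring at least seven volumes with at least one b = 0. Negative
eigenvalues (a noise artefact) are retained but flagged, not clipped;
clipping would bias RD downward. Scalars follow the standard definitions
(AD = λ₁, RD = (λ₂+λ₃)/2, MD = mean, FA = normalized eigenvalue
dispersion, set to 0 with a flag for an all-zero tensor).

The pathway measure is ⟨D⟩ = Σ D·w·WM / Σ w·WM by default. The normalizing
denominator makes ⟨D⟩ a true weighted average: insensitive to the overall
scaling of the track map and comparable across subjects with different
tract sizes, which is what "pathway-averaged" RD requires. The literal
unnormalized weighted sum is available behind `normalized=False` for
comparison. Track maps may arrive as probabilities in [0, 1] or as raw
visitation counts; count-dialect maps (max > 1) are rescaled by their
maximum with a log notice.

## Cohort statistics

* **Motion gating.** A scan fails QC when TDzmax > 1 mm AND
  TDzmean > 0.2 mm (conjunction; a disjunctive mode exists for sensitivity
  analysis). A failed baseline withdraws the participant; a failed
  follow-up flags the scan for visual inspection.
* **Exclusion accounting.** Participant flags (withdrew, depression-score
  removal, low baseline cognition, baseline motion) and visit-level events
  (early truncation, missing acquisitions, connectivity-scan artefacts)
  are reduced to an ordered ledger per group: enrolled → after withdrawals
  → after administrative removals → final N, and scheduled → truncated →
  removed → usable visits → usable connectivity scans.
  `printed_study_cohort()` encodes the published enrollment facts of the
  motivating study as inputs to this accounting.
* **Longitudinal slopes.** A linear mixed model with random intercept and
  slope per subject, fit by maximum likelihood (not REML — REML
  likelihoods are not comparable across fixed-effect structures), with a
  likelihood-ratio test dropping every fixed term containing the test term
  against a χ² reference with df = parameters dropped. Per-subject slopes
  are BLUP-style (fixed slope + random deviation). If the optimizer fails
  to converge, a per-subject-OLS fallback (slopes summarized by mean and
  SE, Wald statistic against χ²₁) is returned with a provenance tag.
  Visit index is treated as continuous.
* **FDR.** Benjamini–Hochberg step-up; the family is caller-declared
  because different analyses group tests differently.
* **Behaviour correlations.** Pearson r with two-sided p; timed motor
  scores are natural-log-transformed first, and subjects beyond 3 SD from
  the mean of the transformed score are excluded (reported by id).

## Synthetic data

**Measure-level cohorts.** The generator draws, per subject × pathway,
normal baselines and per-group normal slopes, then visit values
baseline + slope·visit + independent noise. Defaults are the study
conditions: 20 progressors vs 9 stable subjects, up to nine time points,
fc baseline 1.5 ± 0.4 z (a connected pathway sits well above the
whole-brain mean), RD baseline 0.5×10⁻³ ± 0.05×10⁻³ mm²/s (healthy deep
white matter), progressor slopes −0.05 z/visit (fc) and +0.01×10⁻³
mm²/s/visit (RD) with between-subject SDs of 0.02 and 0.004×10⁻³, stable
slopes zero-mean with small jitter, and visit-level noise 0.15 z /
0.015×10⁻³ mm²/s. Random slopes are untruncated normals. Two scenarios:
`uniform_decline` applies the progressor slopes to all pathways;
`domain_specific` to the cognitive pathways only. The candidate measures
compared by ROC are M1 = the full combined index, M2 = an fc-only
composite, M3 = an sc-only composite; progression scores are negative
per-subject OLS slopes of the measure over the first t visits, and AUC is
the tie-aware Mann–Whitney statistic. These definitions and effect sizes
are this package's reconstruction of a development-stage simulation whose
exact parameters were never printed; results characterize the
reconstruction, not the original design.

**Volume-level fixtures.** Small geometrically consistent NIfTI sets: a
resting series whose 9-voxel seed and target share a band-limited
(< 0.06 Hz, so it survives the temporal filter) latent signal at a
configurable correlation ρ on top of white noise; a task series with a
planted boxcar activation; an RD map with an elevated-diffusivity tract
whose smooth track probability map is supported entirely inside the
constant-RD region (making the weighted average exactly recoverable); and
binary brain/GM/WM masks. A manifest records every planted truth.

**What passing tests show.** The synthetic volumes contain none of the
structure that makes real fMRI/DWI hard: no physiological noise spectra,
motion, susceptibility distortion, spatial autocorrelation of noise,
partial-volume effects, or lesions. Tests on them establish that the
arithmetic of the pipeline is correct and that planted effects of known
size are recovered — not that the index behaves as reported on acquired
data.

## Numerical choices and problem sizes

* Zero-variance voxels get r = 0 with an `invalid` flag rather than NaN;
  a zero-variance reference or a degenerate (constant) t map is an error.
* |r| = 1 maps to ±t_cap (default 10⁶) rather than ±∞.
* A 4-D file with header TR 0 is rejected unless the TR is supplied
  explicitly: temporal filtering needs a trusted sampling rate.
* Monte-Carlo suites run at desk scale, chosen so the full test suite
  completes in minutes on one CPU: 50 fixture replicates for
  planted-correlation recovery, 100 cohorts for slope recovery, 300 for
  LRT type-I calibration, 200–500 for the AUC calibration and
  monotonicity sweeps, on 16×16×6×60 fixture volumes and 29-subject
  simulated cohorts.

## Known limitations

* Registration estimation, tractography, segmentation, physiological-noise
  regression, and motion correction are out of scope: affines, track maps,
  masks, and preprocessed series are inputs.
* The mixed-model path delegates to a standard REML/ML estimator; small
  samples with near-degenerate random-effect covariances can fail to
  converge, in which case the documented OLS fallback is used.
* The effective temporal dof after low-pass filtering is not estimated;
  the t-scale is therefore only defined up to the monotone map removed by
  z-normalization.
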