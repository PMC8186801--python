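"""Cohort quality control, longitudinal slope models, FDR, and behaviour correlations.

Covers the study-level statistics layer around the connectivity metric:
motion-based scan gating, the participant/visit exclusion accounting, linear
mixed-effects slope estimation with likelihood-ratio model comparison,
Benjamini-Hochberg FDR, and Pearson imaging-behaviour correlations with the
log-transform and 3-SD outlier rules used for motor timing measures.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MotionSummary",
    "ParticipantRecord",
    "SlopeEstimate",
    "FLAG_VOCABULARY",
    "motion_gate",
    "exclusion_cascade",
    "printed_study_cohort",
    "fit_longitudinal",
    "bh_fdr",
    "behavior_correlation",
]


# ---------------------------------------------------------------------------
# Motion QC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotionSummary:
    """Residual voxel displacement after motion correction, in mm."""

    subject: str
    visit: int
    td_zmean: float
    td_zmax: float

    def __post_init__(self) -> None:
        if self.td_zmean < 0 or self.td_zmax < 0:
            raise ValueError("displacements must be non-negative")
        if self.td_zmax < self.td_zmean:
            raise ValueError("td_zmax cannot be below td_zmean")


def motion_gate(ms: MotionSummary, is_baseline: bool,
                zmax_mm: float = 1.0, zmean_mm: float = 0.2,
                conjunctive: bool = True) -> str:
    """Gate a scan on residual motion: ``pass``, ``withdraw``, or ``flag``.

    The criterion is TDzmax > 1 mm *and* TDzmean > 0.2 mm (a conjunction;
    a disjunctive mode exists for sensitivity analysis). Baseline scans over
    threshold withdraw the participant; follow-up scans are flagged for
    visual inspection of the time series and correlation maps.
    """
    over_max = ms.td_zmax > zmax_mm
    over_mean = ms.td_zmean > zmean_mm
    over = (over_max and over_mean) if conjunctive else (over_max or over_mean)
    if not over:
        return "pass"
    return "withdraw" if is_baseline else "flag"


# ---------------------------------------------------------------------------
# Exclusion accounting
# ---------------------------------------------------------------------------

FLAG_VOCABULARY = frozenset({
    "withdrew",              # left the study before completion
    "bdi_over_20",           # administrative removal: depression score
    "low_baseline_cognition",  # administrative removal (controls)
    "baseline_motion",       # administrative withdrawal: failed baseline motion gate
})

#: participant-level flags counted as administrative removals (vs withdrawal)
_ADMIN_FLAGS = frozenset({"bdi_over_20", "low_baseline_cognition", "baseline_motion"})


@dataclasses.dataclass
class ParticipantRecord:
    """One enrolled participant's accounting facts.

    ``n_visits_completed`` < ``n_visits_scheduled`` encodes retained
    participants who stopped attending early; ``visit_removals`` lists
    reasons for individually removed visits (e.g. a missing DTI
    acquisition); ``connectivity_excluded_visits`` counts usable visits
    whose connectivity scan failed visual motion inspection.
    """

    subject: str
    group: str  # "MS" | "HC"
    status_flags: Tuple[str, ...] = ()
    n_visits_scheduled: int = 6
    n_visits_completed: int | None = None
    visit_removals: Tuple[str, ...] = ()
    connectivity_excluded_visits: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.status_flags) - FLAG_VOCABULARY
        if unknown:
            raise ValueError(f"unknown status flags {sorted(unknown)}")
        if self.n_visits_completed is None:
            self.n_visits_completed = self.n_visits_scheduled

    @property
    def retained(self) -> bool:
        return not self.status_flags

    @property
    def usable_visits(self) -> int:
        return self.n_visits_completed - len(self.visit_removals)


def exclusion_cascade(records: Iterable[ParticipantRecord]) -> Dict[str, Dict[str, int]]:
    """Ordered participant/visit/connectivity-scan accounting per group.

    Returns a nested dict ``{group: ledger}`` where each ledger carries the
    counts at every stage: enrolled -> after withdrawals -> after
    administrative removals -> final N; scheduled visits -> after
    participant truncation -> after visit-level removals -> usable visits;
    and usable connectivity scans after motion/artefact exclusion.
    """
    records = list(records)
    ledgers: Dict[str, Dict[str, int]] = {}
    for group in sorted({r.group for r in records}):
        grp = [r for r in records if r.group == group]
        withdrew = [r for r in grp if "withdrew" in r.status_flags]
        after_withdrawals = [r for r in grp if "withdrew" not in r.status_flags]
        admin = [r for r in after_withdrawals if set(r.status_flags) & _ADMIN_FLAGS]
        final = [r for r in after_withdrawals if r.retained]
        scheduled = sum(r.n_visits_scheduled for r in final)
        after_trunc = sum(r.n_visits_completed for r in final)
        usable = sum(r.usable_visits for r in final)
        conn_excluded = sum(r.connectivity_excluded_visits for r in final)
        ledgers[group] = {
            "enrolled": len(grp),
            "withdrew": len(withdrew),
            "after_withdrawals": len(after_withdrawals),
            "administrative_removals": len(admin),
            "final_n": len(final),
            "visits_scheduled": scheduled,
            "visits_after_truncation": after_trunc,
            "visit_removals": after_trunc - usable,
            "usable_visits": usable,
            "connectivity_excluded": conn_excluded,
            "usable_connectivity_scans": usable - conn_excluded,
        }
    return ledgers


def printed_study_cohort() -> List[ParticipantRecord]:
    """The study's published enrollment/exclusion facts as participant records.

    Inputs to the accounting, not outputs: 25 MS enrolled (2 withdrew, 2
    removed for BDI > 20, 1 for baseline motion; one retained participant
    completed 4 of 6 visits and one lost a visit to a failed DTI
    acquisition; 3 retained visits lost their connectivity scan to motion
    artefact) and 12 controls enrolled (1 withdrew, 2 removed for low
    baseline cognition), each control scheduled for 2 visits.
    """
    ms: List[ParticipantRecord] = []
    ms += [ParticipantRecord(f"MS{i:02d}", "MS", ("withdrew",)) for i in (1, 2)]
    ms += [ParticipantRecord(f"MS{i:02d}", "MS", ("bdi_over_20",)) for i in (3, 4)]
    ms += [ParticipantRecord("MS05", "MS", ("baseline_motion",))]
    ms += [ParticipantRecord("MS06", "MS", n_visits_completed=4)]
    ms += [ParticipantRecord("MS07", "MS", visit_removals=("missing_dti",),
                             connectivity_excluded_visits=0)]
    # three retained participants each lost one connectivity scan to artefact
    ms += [ParticipantRecord(f"MS{i:02d}", "MS", connectivity_excluded_visits=1)
           for i in (8, 9, 10)]
    ms += [ParticipantRecord(f"MS{i:02d}", "MS") for i in range(11, 26)]
    hc: List[ParticipantRecord] = []
    hc += [ParticipantRecord("HC01", "HC", ("withdrew",), n_visits_scheduled=2)]
    hc += [ParticipantRecord(f"HC{i:02d}", "HC", ("low_baseline_cognition",),
                             n_visits_scheduled=2) for i in (2, 3)]
    hc += [ParticipantRecord(f"HC{i:02d}", "HC", n_visits_scheduled=2)
           for i in range(4, 13)]
    return ms + hc


# ---------------------------------------------------------------------------
# Longitudinal slope models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SlopeEstimate:
    """Fixed-effect slope, per-subject slopes, and the full-vs-reduced LRT."""

    measure_name: str
    fixed_slope: float
    subject_slopes: Dict[str, float]
    covariates_used: List[str]
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    method: str  # "lme" | "ols_fallback"
    converged: bool


def _ols_fallback(df: pd.DataFrame, value_col: str, time_col: str,
                  measure_name: str, covariates: List[str]) -> SlopeEstimate:
    slopes = {}
    for subject, grp in df.groupby("subject"):
        if grp[time_col].nunique() < 2:
            continue
        slopes[str(subject)] = float(np.polyfit(grp[time_col], grp[value_col], 1)[0])
    vals = np.array(list(slopes.values()))
    if len(vals) < 2:
        raise ValueError("fallback slope summary needs >= 2 subjects with >= 2 visits")
    mean, se = vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals))
    stat = float((mean / se) ** 2) if se > 0 else np.inf
    p = float(sps.chi2.sf(stat, 1))
    return SlopeEstimate(measure_name, float(mean), slopes, covariates,
                         stat, 1, p, "ols_fallback", converged=False)


def fit_longitudinal(data: pd.DataFrame, value_col: str = "value",
                     time_col: str = "visit",
                     covariates: Sequence[str] = (),
                     test_term: str | None = None,
                     measure_name: str = "") -> SlopeEstimate:
    """Random-intercept-and-slope mixed model with a full-vs-reduced LRT.

    The full fixed-effects structure is ``value ~ time + covariates``
    (plus any interaction terms passed in `covariates`, e.g. ``"group"``
    and ``"group:visit"`` for a group contrast). The reduced model drops
    every fixed term containing ``test_term`` (default: the time column)
    and the two ML fits — maximum likelihood, not REML, since REML
    likelihoods are not comparable across fixed-effect structures — are
    compared by 2·Δll against a chi-square with df = parameters dropped.

    Per-subject slopes are BLUP-style: the fixed time coefficient plus each
    subject's random slope deviation. On non-convergence the per-subject
    OLS fallback is returned, tagged ``method="ols_fallback"``.
    """
    # interaction terms like "group:visit" are formula-only, not columns
    cov_cols = [c for c in covariates if c in data.columns]
    df = data.dropna(subset=[value_col, time_col] + cov_cols).copy()
    n_sub = df["subject"].nunique()
    if n_sub < 2:
        raise ValueError("mixed model needs >= 2 subjects")
    if (df.groupby("subject")[time_col].nunique() < 2).all():
        raise ValueError("no subject has >= 2 distinct visits")
    test_term = test_term or time_col
    full_terms = [time_col] + list(covariates)
    reduced_terms = [t for t in full_terms if test_term not in t]

    def _fit(terms: List[str]):
        rhs = " + ".join(terms) if terms else "1"
        model = MixedLM.from_formula(
            f"{value_col} ~ {rhs}", groups="subject",
            re_formula=f"~{time_col}", data=df)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=False, method=["powell", "lbfgs", "cg"], maxiter=500)

    try:
        full = _fit(full_terms)
        reduced = _fit(reduced_terms)
        converged = bool(full.converged and reduced.converged)
    except Exception:
        converged = False
    if not converged:
        return _ols_fallback(df, value_col, time_col, measure_name, list(covariates))

    lrt_df = int(full.k_fe - reduced.k_fe)
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(sps.chi2.sf(stat, max(lrt_df, 1)))
    fixed_slope = float(full.fe_params.get(time_col, np.nan))
    slopes = {}
    for subject, re in full.random_effects.items():
        slopes[str(subject)] = fixed_slope + float(re.get(time_col, 0.0))
    return SlopeEstimate(measure_name, fixed_slope, slopes, list(covariates),
                         float(stat), lrt_df, p, "lme", converged=True)


# ---------------------------------------------------------------------------
# Multiple testing and correlations
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def behavior_correlation(x: Sequence[float], y: Sequence[float],
                         ids: Sequence[str] | None = None,
                         log_transform_y: bool = False,
                         outlier_sd: float = 3.0):
    """Pearson correlation with the motor-timing transform and outlier rules.

    Optionally natural-log-transforms y (used for timed motor scores), then
    excludes subjects whose transformed y lies more than ``outlier_sd``
    standard deviations from the sample mean, and returns
    ``(r, p, n_used, excluded_ids)`` on the remainder.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(x))]
    keep = np.isfinite(x) & np.isfinite(y)
    if log_transform_y:
        if np.any(y[keep] <= 0):
            raise ValueError("log transform requires positive y")
        y = np.where(keep, np.log(np.where(keep, y, 1.0)), y)
    yk = y[keep]
    mu, sd = yk.mean(), yk.std(ddof=1)
    if sd > 0:
        outlier = keep & (np.abs(y - mu) > outlier_sd * sd)
    else:
        outlier = np.zeros_like(keep)
    use = keep & ~outlier
    excluded = [ids[i] for i in np.flatnonzero(outlier)]
    if use.sum() < 4:
        raise ValueError(f"only {int(use.sum())} pairs remain after exclusion; need >= 4")
    r, p = sps.pearsonr(x[use], y[use])
    return float(r), float(p), int(use.sum()), excluded
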