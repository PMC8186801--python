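"""The Structural and Functional Connectivity Index (SFCI).

Each pathway contributes a component score that averages the z-scored
functional connectivity fc and z-scored structural connectivity sc against
a normative sample:

    Z = 1/2 [ s_fc (fc - fc_pop)/sigma_fc + s_sc (sc - sc_pop)/sigma_sc ]

The composite combines the motor (transcallosal SMC) component with the
worse (minimum) of the two hemispheric cognitive (PCC-AMTL) components:

    SFCI = 1/2 Z_motor + 1/2 min(Z_cog_L, Z_cog_R)

Orientation signs: sc is radial diffusivity, which *rises* with
demyelination while fc *falls*, so the default orientation negates the
structural z (s_fc = +1, s_sc = -1) and both components decline with
impairment — consistent with a metric that is lower in patients and
positively correlated with behavioural performance. The literal
equal-signs form (both +1) remains available via ``orientation="literal"``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MOTOR_PATHWAY",
    "COG_LEFT",
    "COG_RIGHT",
    "PATHWAYS",
    "NormativeStats",
    "SFCIScore",
    "compute_norms",
    "z_component",
    "combine_sfci",
    "score_cohort",
    "measures_frame",
]

MOTOR_PATHWAY = "SMC_transcallosal"
COG_LEFT = "PCC_AMTL_L"
COG_RIGHT = "PCC_AMTL_R"
PATHWAYS = (MOTOR_PATHWAY, COG_LEFT, COG_RIGHT)

MEASURE_COLUMNS = ["subject", "visit", "pathway", "fc", "sc"]

_ORIENTATIONS = {"default": (1.0, -1.0), "literal": (1.0, 1.0)}


class DegenerateNormsError(ValueError):
    """Raised when a norming sample has zero variance on any component."""


def measures_frame(records: Iterable[dict] | pd.DataFrame) -> pd.DataFrame:
    """Coerce pathway measures into the tidy (subject, visit, pathway, fc, sc) frame."""
    df = pd.DataFrame(records)
    missing = [c for c in MEASURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measures missing columns {missing}")
    if df.duplicated(["subject", "visit", "pathway"]).any():
        raise ValueError("duplicate (subject, visit, pathway) records")
    if not np.isfinite(df[["fc", "sc"]].to_numpy(float)).all():
        raise ValueError("non-finite fc/sc values")
    return df[MEASURE_COLUMNS + [c for c in df.columns if c not in MEASURE_COLUMNS]]


@dataclasses.dataclass
class NormativeStats:
    """Per-pathway normative means/SDs of fc and sc plus orientation signs."""

    table: pd.DataFrame  # index pathway; columns fc_mean, fc_sd, sc_mean, sc_sd
    orientation: str = "default"
    source: str = ""

    def __post_init__(self) -> None:
        need = {"fc_mean", "fc_sd", "sc_mean", "sc_sd"}
        if not need <= set(self.table.columns):
            raise ValueError(f"norms table needs columns {sorted(need)}")
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(f"unknown orientation '{self.orientation}'")
        if (self.table[["fc_sd", "sc_sd"]] <= 0).any().any():
            raise DegenerateNormsError("normative SDs must be positive")

    @property
    def signs(self) -> Tuple[float, float]:
        return _ORIENTATIONS[self.orientation]

    def for_pathway(self, pathway: str) -> pd.Series:
        if pathway not in self.table.index:
            raise KeyError(f"pathway '{pathway}' absent from norms")
        return self.table.loc[pathway]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "pathway", out.index)
        with open(path, "w") as fh:
            fh.write(f"# orientation: {self.orientation}\n# source: {self.source}\n")
            out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "NormativeStats":
        orientation, source = "default", ""
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("# orientation:"):
                orientation = line.split(":", 1)[1].strip()
            elif line.startswith("# source:"):
                source = line.split(":", 1)[1].strip()
            elif not line.startswith("#"):
                body.append(line)
        import io
        table = pd.read_csv(io.StringIO("".join(body))).set_index("pathway")
        table.index.name = None
        return cls(table=table, orientation=orientation, source=source)


@dataclasses.dataclass
class SFCIScore:
    z_motor: float
    z_cog_l: float
    z_cog_r: float
    sfci: float
    subject: str = ""
    visit: int = 0

    def __post_init__(self) -> None:
        expected = 0.5 * self.z_motor + 0.5 * min(self.z_cog_l, self.z_cog_r)
        if abs(self.sfci - expected) > 1e-12:
            raise ValueError("sfci field inconsistent with its components")


def compute_norms(controls: pd.DataFrame, orientation: str = "default",
                  source: str = "control sample") -> NormativeStats:
    """Per-pathway sample mean and SD (N-1 denominator) of fc and sc.

    The norming sample is typically the healthy-control baseline visits; pass
    whichever subset of measures defines the normative population.
    """
    df = measures_frame(controls)
    rows = {}
    for pathway, grp in df.groupby("pathway"):
        if grp["subject"].nunique() < 2:
            raise ValueError(f"pathway '{pathway}': need >= 2 norming subjects")
        rows[pathway] = {
            "fc_mean": grp["fc"].mean(), "fc_sd": grp["fc"].std(ddof=1),
            "sc_mean": grp["sc"].mean(), "sc_sd": grp["sc"].std(ddof=1),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if (table[["fc_sd", "sc_sd"]] <= 1e-300).any().any():
        raise DegenerateNormsError("zero variance in the norming sample")
    return NormativeStats(table=table, orientation=orientation, source=source)


def z_component(fc: float, sc: float, pathway: str, norms: NormativeStats) -> float:
    """One pathway's component score: the mean of the oriented fc and sc z-scores."""
    row = norms.for_pathway(pathway)
    s_fc, s_sc = norms.signs
    return 0.5 * (s_fc * (fc - row["fc_mean"]) / row["fc_sd"]
                  + s_sc * (sc - row["sc_mean"]) / row["sc_sd"])


def combine_sfci(z_motor: float, z_cog_l: float, z_cog_r: float,
                 subject: str = "", visit: int = 0) -> SFCIScore:
    """SFCI = 1/2 Z_motor + 1/2 min(Z_cog_L, Z_cog_R)."""
    for name, v in (("z_motor", z_motor), ("z_cog_l", z_cog_l), ("z_cog_r", z_cog_r)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite")
    sfci = 0.5 * z_motor + 0.5 * min(z_cog_l, z_cog_r)
    return SFCIScore(z_motor=z_motor, z_cog_l=z_cog_l, z_cog_r=z_cog_r,
                     sfci=sfci, subject=subject, visit=visit)


def score_cohort(measures: pd.DataFrame, norms: NormativeStats
                 ) -> Tuple[pd.DataFrame, List[dict]]:
    """Score every complete subject-visit; report incomplete ones.

    A visit must carry all three pathways; visits missing any pathway
    (including a single cognitive hemisphere — min() over one value would
    silently change the estimand) are skipped and listed in the report.

    Returns
    -------
    scores : DataFrame with columns subject, visit, z_motor, z_cog_l,
        z_cog_r, sfci.
    skipped : list of {"subject", "visit", "missing"} dicts.
    """
    df = measures_frame(measures)
    scores, skipped = [], []
    for (subject, visit), grp in df.groupby(["subject", "visit"], sort=True):
        present = set(grp["pathway"])
        missing = [p for p in PATHWAYS if p not in present]
        if missing:
            skipped.append({"subject": subject, "visit": visit, "missing": missing})
            continue
        by = grp.set_index("pathway")
        comps = {p: z_component(by.loc[p, "fc"], by.loc[p, "sc"], p, norms)
                 for p in PATHWAYS}
        score = combine_sfci(comps[MOTOR_PATHWAY], comps[COG_LEFT], comps[COG_RIGHT],
                             subject=subject, visit=visit)
        scores.append({"subject": subject, "visit": visit,
                       "z_motor": score.z_motor, "z_cog_l": score.z_cog_l,
                       "z_cog_r": score.z_cog_r, "sfci": score.sfci})
    cols = ["subject", "visit", "z_motor", "z_cog_l", "z_cog_r", "sfci"]
    return pd.DataFrame(scores, columns=cols), skipped
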