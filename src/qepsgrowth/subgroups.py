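"""Subgroup classification and subgroup median curves with bootstrap CIs.

Subjects are classified on three criteria, each with thresholds applied as
strict inequalities (ties fall in ``uncategorized``):

* pubertal timing - deviation of AgeTPHV from the sex mean of the analysis
  cohort: early < -1.5 y, late > +1.5 y, average within +/-0.25 y;
* stature at onset - height SDS at the individual's AgeP5 against the
  C-age height reference: tall > +1.5 SDS, short < -1.5 SDS;
* childhood BMI - maximum fitted BMI SDS over the childhood window
  (girls 3.5-7 y, boys 3.5-8 y): high > +1.5 SDS, low < -1.5 SDS.

Group curves are subject-level bootstrap medians (resampling subjects with
replacement, percentile CIs) evaluated against a reference, in native units
and in SDS.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .references import ReferenceTable, align_to_page, sds_lookup

__all__ = [
    "SubgroupLabel",
    "classify_timing",
    "classify_stature",
    "classify_childhood_bmi",
    "height_sds_at_onset",
    "classify_cohort",
    "group_curves",
    "CHILDHOOD_BMI_WINDOW",
]

TIMING_EXTREME = 1.5      # years
TIMING_AVERAGE = 0.25     # years
SDS_THRESHOLD = 1.5

CHILDHOOD_BMI_WINDOW = {"F": (3.5, 7.0), "M": (3.5, 8.0)}


@dataclass(frozen=True)
class SubgroupLabel:
    criterion: str   # timing | stature | childhoodBMI
    category: str

    _ALLOWED = {
        "timing": ("early", "average", "late", "uncategorized"),
        "stature": ("tall", "short", "uncategorized"),
        "childhoodBMI": ("high", "low", "uncategorized"),
    }

    def __post_init__(self) -> None:
        if self.criterion not in self._ALLOWED:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.category not in self._ALLOWED[self.criterion]:
            raise ValueError(
                f"category {self.category!r} invalid for {self.criterion}")


def classify_timing(age_tphv: float, sex_mean_age_tphv: float) -> SubgroupLabel:
    """Early/average/late pubertal timing by AgeTPHV deviation from the sex
    mean; the gap between |d| = 0.25 and 1.5 y is uncategorized."""
    d = age_tphv - sex_mean_age_tphv
    if not np.isfinite(d):
        return SubgroupLabel("timing", "uncategorized")
    if d < -TIMING_EXTREME:
        cat = "early"
    elif d > TIMING_EXTREME:
        cat = "late"
    elif abs(d) <= TIMING_AVERAGE:
        cat = "average"
    else:
        cat = "uncategorized"
    return SubgroupLabel("timing", cat)


def classify_stature(height_sds_at_onset: float) -> SubgroupLabel:
    """Tall/short by height SDS at onset of puberty (strict +/-1.5)."""
    s = height_sds_at_onset
    if not np.isfinite(s):
        return SubgroupLabel("stature", "uncategorized")
    if s > SDS_THRESHOLD:
        cat = "tall"
    elif s < -SDS_THRESHOLD:
        cat = "short"
    else:
        cat = "uncategorized"
    return SubgroupLabel("stature", cat)


def height_sds_at_onset(subject, height_ref_cage: ReferenceTable) -> float:
    """Height SDS of the fitted total-height curve at the subject's AgeP5."""
    p5 = subject.age_p5
    if not np.isfinite(p5):
        return float("nan")
    p5 = float(np.clip(p5, height_ref_cage.grid[0], height_ref_cage.grid[-1]))
    value = subject.curve("height").value(p5, "total")
    return sds_lookup(height_ref_cage, p5, value)


def classify_childhood_bmi(subject, bmi_ref_cage: ReferenceTable) -> SubgroupLabel:
    """High/low childhood BMI from the maximum fitted BMI SDS over the
    sex-specific childhood window on a 0.1-y grid."""
    if getattr(subject, "weight_params", None) is None:
        return SubgroupLabel("childhoodBMI", "uncategorized")
    lo, hi = CHILDHOOD_BMI_WINDOW[subject.sex]
    if lo < bmi_ref_cage.grid[0] or hi > bmi_ref_cage.grid[-1]:
        raise ValueError("childhood window lies outside the BMI reference grid")
    ages = np.round(np.arange(lo, hi + 1e-9, 0.1), 10)
    vals = subject.curve("bmi").value(ages)
    worst = float(np.max(sds_lookup(bmi_ref_cage, ages, vals)))
    if worst > SDS_THRESHOLD:
        cat = "high"
    elif worst < -SDS_THRESHOLD:
        cat = "low"
    else:
        cat = "uncategorized"
    return SubgroupLabel("childhoodBMI", cat)


def classify_cohort(subjects: Sequence, height_ref: dict,
                    bmi_ref: dict) -> pd.DataFrame:
    """Classify every subject on all three criteria.

    ``height_ref`` and ``bmi_ref`` map sex to the C-age total reference.
    The timing criterion uses the analysis cohort's own per-sex mean
    AgeTPHV.  Returns long-format (subject_id, criterion, category).
    """
    mean_tphv = {}
    for sex in ("F", "M"):
        vals = [s.landmarks.age_tphv for s in subjects
                if s.sex == sex and s.landmarks and np.isfinite(s.landmarks.age_tphv)]
        mean_tphv[sex] = float(np.mean(vals)) if vals else float("nan")
    rows = []
    for s in subjects:
        tphv = s.landmarks.age_tphv if s.landmarks else float("nan")
        labels = [classify_timing(tphv, mean_tphv[s.sex]),
                  classify_stature(height_sds_at_onset(s, height_ref[s.sex]))]
        if s.sex in bmi_ref and getattr(s, "weight_params", None) is not None:
            labels.append(classify_childhood_bmi(s, bmi_ref[s.sex]))
        for lab in labels:
            rows.append(dict(subject_id=s.subject_id, criterion=lab.criterion,
                             category=lab.category))
    return pd.DataFrame(rows, columns=["subject_id", "criterion", "category"])


MIN_STABLE_GROUP = 5


def group_curves(group: Sequence, reference: ReferenceTable,
                 nboot: int = 500, seed: int = 0,
                 component: Optional[str] = None) -> pd.DataFrame:
    """Median curve of a subject group with bootstrap 95% CI, against a
    reference, in native units and SDS.

    Subject-level bootstrap: subjects are resampled with replacement
    ``nboot`` times (seeded); CIs are percentile intervals of the bootstrap
    medians.  Groups smaller than 5 subjects are flagged unstable.
    Evaluated on the reference's own axis and grid.
    """
    group = list(group)
    if not group:
        raise ValueError("empty subject group")
    comp = component or reference.component
    grid = reference.grid
    values = np.empty((len(group), grid.size))
    for i, s in enumerate(group):
        curve = s.curve(reference.variable)
        if reference.axis == "cage":
            values[i] = curve.value(grid, comp)
        else:
            values[i] = align_to_page(curve, s.age_p5, grid, comp)
    med = np.nanmedian(values, axis=0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(group), size=(nboot, len(group)))
    boot_meds = np.nanmedian(values[idx], axis=1)
    lo, hi = np.nanpercentile(boot_meds, [2.5, 97.5], axis=0)

    out = pd.DataFrame({
        "sex": reference.sex, "variable": reference.variable,
        "component": comp, "axis": reference.axis, "age": grid,
        "median": med, "ci_lo": lo, "ci_hi": hi,
        "median_sds": sds_lookup(reference, grid, med),
        "sds_lo": sds_lookup(reference, grid, lo),
        "sds_hi": sds_lookup(reference, grid, hi),
    })
    out.attrs["n_subjects"] = len(group)
    out.attrs["unstable_ci"] = len(group) < MIN_STABLE_GROUP
    return out
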