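"""Construction of median/SDS growth references on two age axes.

A reference is built from a cohort of *fitted* curves (no residual
measurement noise): at every grid age the empirical percentiles
{2.28, 15.87, 50, 84.13, 97.72} of the curve values across subjects are
taken - these correspond to SDS -2..+2 - and smoothed along age by a local
linear kernel regression whose shared weights preserve the percentile
ordering.

Two axes are supported:

* ``cage`` - chronological (GA-corrected) age, grid 4..20 y;
* ``page`` - puberty-adjusted age, grid -4..+10 y around each individual's
  onset of the pubertal growth spurt (AgeP5), so that every subject's
  spurt is superimposed at 0.

SDS scoring maps a value through the interpolated empirical percentile set
with a piecewise-linear quantile function (linearly extrapolated in the
tails using the adjacent tail spacing), which makes ``sds_lookup`` and
``value_at_sds`` exact inverses.  BMI references are tabulated on the
native kg^0.5/m scale with conventional kg/m^2 columns obtained by
squaring.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_T0

__all__ = [
    "PERCENTILE_COLUMNS",
    "SDS_LEVELS",
    "ReferenceTable",
    "cage_grid",
    "page_grid",
    "align_to_page",
    "build_reference",
    "sds_lookup",
    "value_at_sds",
    "variance_ratio",
]

#: SDS levels of the tabulated percentile set
SDS_LEVELS = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
#: exact normal tail probabilities (percent) for the SDS levels
PERCENTILE_PROBS = np.array([2.275013, 15.865525, 50.0, 84.134475, 97.724987])
PERCENTILE_COLUMNS = ("p2_28", "p15_87", "p50", "p84_13", "p97_72")

# starts below 4 y so the childhood BMI window (from 3.5 y) is scoreable;
# charts display 4-20 y
CAGE_RANGE = (3.5, 20.0)
PAGE_RANGE = (-4.0, 10.0)
GRID_STEP = 0.1

#: smoothing bandwidths (y) per axis for the percentile curves
BANDWIDTH = {"cage": 1.0, "page": 0.5}

MIN_REFERENCE_SUBJECTS = 100


def cage_grid() -> np.ndarray:
    return np.round(np.arange(CAGE_RANGE[0], CAGE_RANGE[1] + 1e-9, GRID_STEP), 10)


def page_grid() -> np.ndarray:
    return np.round(np.arange(PAGE_RANGE[0], PAGE_RANGE[1] + 1e-9, GRID_STEP), 10)


@dataclass
class ReferenceTable:
    """Sex-, variable- and component-specific percentile table on one axis."""

    sex: str
    variable: str            # height | weight | bmi
    component: str           # total | QE | QES | P
    axis: str                # cage | page
    grid: np.ndarray
    percentiles: np.ndarray  # (len(grid), 5), native scale
    n_subjects: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.percentiles = np.asarray(self.percentiles, float)
        if self.percentiles.shape != (self.grid.size, SDS_LEVELS.size):
            raise ValueError("percentile array shape does not match grid")
        if np.any(np.diff(self.percentiles, axis=1) <= 0):
            raise ValueError("percentiles must be strictly increasing at every age")

    @property
    def median(self) -> np.ndarray:
        return self.percentiles[:, 2]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sex": self.sex, "variable": self.variable,
                           "component": self.component, "axis": self.axis,
                           "age": self.grid})
        for j, c in enumerate(PERCENTILE_COLUMNS):
            df[c] = self.percentiles[:, j]
        if self.variable == "bmi":
            for j, c in enumerate(PERCENTILE_COLUMNS):
                df[c + "_kgm2"] = self.percentiles[:, j] ** 2
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: Optional[dict] = None
                   ) -> "ReferenceTable":
        head = df.iloc[0]
        perc = df[list(PERCENTILE_COLUMNS)].to_numpy(float)
        return cls(sex=str(head["sex"]), variable=str(head["variable"]),
                   component=str(head["component"]), axis=str(head["axis"]),
                   grid=df["age"].to_numpy(float), percentiles=perc,
                   n_subjects=(meta or {}).get("n_subjects", 0),
                   meta=meta or {})


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_to_page(curve, age_p5: float, grid: Optional[np.ndarray] = None,
                  component: str = "total") -> np.ndarray:
    """Evaluate a curve on the P-age grid: value at tau is the curve at
    C-age ``age_p5 + tau``.  Ages before conception are masked to NaN."""
    if not np.isfinite(age_p5):
        raise ValueError("age_p5 must be finite to align a curve")
    if grid is None:
        grid = page_grid()
    t = age_p5 + np.asarray(grid, float)
    t0 = DEFAULT_T0
    hp = getattr(curve, "height_params", None)
    if hp is not None:
        t0 = hp.shape.t0
    out = np.full(t.shape, np.nan)
    ok = t >= -t0
    if np.any(ok):
        out[ok] = curve.value(t[ok], component)
    return out


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _local_linear_smooth(x: np.ndarray, Y: np.ndarray, bandwidth: float
                         ) -> np.ndarray:
    """Gaussian-kernel local linear smoothing of columns of Y along x.

    The same weights are applied to every column, so column ordering (the
    percentile ordering) is preserved wherever the smoother's weights are a
    proper local average.
    """
    out = np.empty_like(Y)
    for i, x0 in enumerate(x):
        u = (x - x0) / bandwidth
        w = np.exp(-0.5 * u * u)
        sw = w.sum()
        s1 = (w * u).sum() / sw
        s2 = (w * u * u).sum() / sw
        # local linear kernel weights (equivalent kernel)
        lw = w * (s2 - u * s1)
        out[i] = lw @ Y / lw.sum()
    return out


def build_reference(subjects: Sequence, sex: str, variable: str,
                    component: str = "total", axis: str = "cage",
                    min_subjects: int = MIN_REFERENCE_SUBJECTS,
                    smooth: bool = True, meta: Optional[dict] = None
                    ) -> ReferenceTable:
    """Build a percentile reference from fitted subjects of one sex.

    ``subjects`` are fitted-subject objects exposing ``sex``, ``curve()``
    and ``age_p5``.  Values are the fitted-curve values (no measurement
    noise); percentiles are empirical across subjects at every grid age.
    """
    if axis not in ("cage", "page"):
        raise ValueError(f"unknown axis {axis!r}")
    grp = [s for s in subjects if s.sex == sex]
    if variable == "bmi":
        grp = [s for s in grp if getattr(s, "weight_params", None) is not None]
    if len(grp) < min_subjects:
        raise ValueError(
            f"need >= {min_subjects} subjects of sex {sex} to build a "
            f"reference, got {len(grp)}")
    grid = cage_grid() if axis == "cage" else page_grid()
    values = np.empty((len(grp), grid.size))
    for i, s in enumerate(grp):
        curve = s.curve(variable)
        if axis == "cage":
            values[i] = curve.value(grid, component)
        else:
            values[i] = align_to_page(curve, s.age_p5, grid, component)
    perc = np.nanpercentile(values, PERCENTILE_PROBS, axis=0).T
    if smooth:
        perc = _local_linear_smooth(grid, perc, BANDWIDTH[axis])
    # numerical guard: enforce a strictly increasing percentile set
    eps = 1e-9 * np.maximum(1.0, np.abs(perc[:, 2:3]))
    for j in range(1, perc.shape[1]):
        perc[:, j] = np.maximum(perc[:, j], perc[:, j - 1] + eps[:, 0])
    info = dict(meta or {})
    info.setdefault("n_subjects", len(grp))
    return ReferenceTable(sex=sex, variable=variable, component=component,
                          axis=axis, grid=grid, percentiles=perc,
                          n_subjects=len(grp), meta=info)


# ---------------------------------------------------------------------------
# SDS scoring
# ---------------------------------------------------------------------------

def _percentiles_at(ref: ReferenceTable, age) -> np.ndarray:
    ages = np.atleast_1d(np.asarray(age, float))
    lo, hi = ref.grid[0], ref.grid[-1]
    if np.any((ages < lo - 1e-9) | (ages > hi + 1e-9)):
        raise ValueError(
            f"age outside reference grid [{lo}, {hi}] on axis {ref.axis}")
    out = np.empty((ages.size, SDS_LEVELS.size))
    for j in range(SDS_LEVELS.size):
        out[:, j] = np.interp(ages, ref.grid, ref.percentiles[:, j])
    return out


def _piecewise_to_sds(v: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Map values to SDS through percentile knots, linear with linear tails."""
    z = np.empty_like(v)
    inner = (v >= knots[:, 0]) & (v <= knots[:, -1])
    for i in range(v.size):
        if inner[i]:
            z[i] = np.interp(v[i], knots[i], SDS_LEVELS)
        elif v[i] < knots[i, 0]:
            slope = (SDS_LEVELS[1] - SDS_LEVELS[0]) / (knots[i, 1] - knots[i, 0])
            z[i] = SDS_LEVELS[0] + (v[i] - knots[i, 0]) * slope
        else:
            slope = (SDS_LEVELS[-1] - SDS_LEVELS[-2]) / (knots[i, -1] - knots[i, -2])
            z[i] = SDS_LEVELS[-1] + (v[i] - knots[i, -1]) * slope
    return z


def sds_lookup(ref: ReferenceTable, age, value):
    """SDS of ``value`` at ``age`` against the reference.

    Normal-quantile mapping through the interpolated empirical percentile
    set; beyond the outer percentiles the mapping extrapolates linearly
    with the adjacent tail spacing.  Exact inverse of :func:`value_at_sds`.
    """
    knots = _percentiles_at(ref, age)
    v = np.broadcast_to(np.asarray(value, float), (knots.shape[0],)).copy()
    z = _piecewise_to_sds(v, knots)
    return float(z[0]) if np.isscalar(value) and np.isscalar(age) else z


def value_at_sds(ref: ReferenceTable, age, sds):
    """Value at a given SDS and age (inverse of :func:`sds_lookup`)."""
    knots = _percentiles_at(ref, age)
    z = np.broadcast_to(np.asarray(sds, float), (knots.shape[0],)).copy()
    v = np.empty_like(z)
    for i in range(z.size):
        if SDS_LEVELS[0] <= z[i] <= SDS_LEVELS[-1]:
            v[i] = np.interp(z[i], SDS_LEVELS, knots[i])
        elif z[i] < SDS_LEVELS[0]:
            slope = (knots[i, 1] - knots[i, 0]) / (SDS_LEVELS[1] - SDS_LEVELS[0])
            v[i] = knots[i, 0] + (z[i] - SDS_LEVELS[0]) * slope
        else:
            slope = (knots[i, -1] - knots[i, -2]) / (SDS_LEVELS[-1] - SDS_LEVELS[-2])
            v[i] = knots[i, -1] + (z[i] - SDS_LEVELS[-1]) * slope
    return float(v[0]) if np.isscalar(sds) and np.isscalar(age) else v


def variance_ratio(ref: ReferenceTable, external: pd.DataFrame) -> pd.DataFrame:
    """Hook comparing reference spread against an externally supplied table.

    ``external`` must have columns ``age``, ``p50``, ``p84_13`` (or ``sd``);
    returns per-age ratio of this reference's half-spread (p84.13 - p50) to
    the external one's.  Intended for variance comparison against an
    LMS-style reference built from the same raw data.
    """
    ext = external.copy()
    if "sd" not in ext.columns:
        ext["sd"] = ext["p84_13"] - ext["p50"]
    ages = ext["age"].to_numpy(float)
    ages = ages[(ages >= ref.grid[0]) & (ages <= ref.grid[-1])]
    knots = _percentiles_at(ref, ages)
    own_sd = knots[:, 3] - knots[:, 2]
    ext_sd = np.interp(ages, ext["age"], ext["sd"])
    return pd.DataFrame({"age": ages, "own_sd": own_sd, "external_sd": ext_sd,
                         "ratio": own_sd / ext_sd})
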