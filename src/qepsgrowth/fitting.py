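"""Per-individual QEPS curve fitting and cohort-level derived quantities.

Height is fitted in cm, weight on the kg^0.5 scale (which makes the
component functions additive).  The model is linear in the three component
amplitudes, so fitting uses variable projection: a bounded nonlinear
least-squares search over the six shape parameters with the amplitudes
profiled out by linear least squares at every step (non-negative least
squares when an amplitude would go negative).  Five seeded multi-starts
guard against local minima; everything is deterministic given the seed.

The weight fit is informed by the height fit: its pubertal timing
parameters start at the fitted height values and are shrunk toward them by
a ridge penalty, operationalising the coupling between the two models.  The
constitutional weight-height factor (WHF) is a cohort-level quantity: a
per-sex regression maps height amplitudes to typical weight amplitudes, and
a subject's WHF is its mean multiplicative deviation from that typical
weight curve (cohort mean 0 by construction).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .core import (
    DEFAULT_T0,
    GrowthCurve,
    PubertyLandmarks,
    QEPSHeightParams,
    QEPSShape,
    QEPSWeightParams,
    _e_u,
    _p_u,
    _q_u,
    _stop_loss_units,
    puberty_landmarks,
)

__all__ = [
    "corrected_age",
    "Measurement",
    "Subject",
    "FitResult",
    "FittedSubject",
    "WhfModel",
    "subjects_from_frame",
    "fit_height",
    "fit_weight",
    "fit_cohort",
    "estimate_whf",
    "predict_weight_amplitudes",
    "whf_for",
    "clean_reference_cohort",
    "fitted_to_frame",
    "fitted_from_frame",
]

GA_TERM_RANGE = (37.0, 43.0)

#: ridge weight for shrinking weight pubertal timing toward the height fit;
#: sized so the penalty contributes roughly a tenth of the data sum of
#: squares on default-noise synthetic cohorts
DEFAULT_WEIGHT_TIMING_LAMBDA = 0.006

N_MULTISTARTS = 5


def corrected_age(postnatal_age: float, ga_weeks: float) -> float:
    """GA-corrected age: postnatal age minus (40 - GA weeks) of gestation.

    Negative near birth for GA < 40.  GA outside [20, 44] weeks is treated
    as implausible and rejected.
    """
    ga = np.asarray(ga_weeks, float)
    if np.any((ga < 20.0) | (ga > 44.0)):
        raise ValueError(f"implausible gestational age {ga_weeks!r} weeks")
    out = np.asarray(postnatal_age, float) - (40.0 - ga) * 7.0 / 365.25
    return float(out) if np.isscalar(postnatal_age) and np.isscalar(ga_weeks) else out


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Measurement:
    """One visit: postnatal age (y) and optional height (cm) / weight (kg)."""

    age: float
    height: Optional[float] = None
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("measurement age must be >= 0")
        if self.height is not None and not 30.0 < self.height < 230.0:
            raise ValueError(f"height {self.height} cm outside plausible range")
        if self.weight is not None and not 0.3 < self.weight < 250.0:
            raise ValueError(f"weight {self.weight} kg outside plausible range")


@dataclass
class Subject:
    """A longitudinal record: id, sex, gestational age, ordered measurements."""

    id: str
    sex: str
    ga_weeks: float
    measurements: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        ages = [m.age for m in self.measurements]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("measurement ages must be strictly increasing")

    @property
    def term_born(self) -> bool:
        return GA_TERM_RANGE[0] <= self.ga_weeks <= GA_TERM_RANGE[1]

    def series(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """(GA-corrected ages, values) for 'height' (cm) or 'weight' (kg)."""
        pairs = [(m.age, getattr(m, variable)) for m in self.measurements
                 if getattr(m, variable) is not None]
        if not pairs:
            return np.empty(0), np.empty(0)
        ages, vals = map(np.asarray, zip(*pairs))
        return corrected_age(ages, self.ga_weeks), np.asarray(vals, float)


def subjects_from_frame(df: pd.DataFrame) -> list[Subject]:
    """Parse a long-format cohort table into Subject objects.

    Expected columns: subject_id, sex, ga_weeks, age_years, height_cm,
    weight_kg (height/weight cells may be empty).
    """
    required = {"subject_id", "sex", "ga_weeks", "age_years"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("age_years")
        meas = []
        for _, r in grp.iterrows():
            h = r.get("height_cm")
            w = r.get("weight_kg")
            meas.append(Measurement(
                age=float(r["age_years"]),
                height=None if pd.isna(h) else float(h),
                weight=None if pd.isna(w) else float(w)))
        out.append(Subject(id=str(sid), sex=str(grp["sex"].iloc[0]),
                           ga_weeks=float(grp["ga_weeks"].iloc[0]),
                           measurements=meas))
    return out


@dataclass
class FitResult:
    """Outcome of one per-subject nonlinear fit."""

    params: object                     # QEPSHeightParams or QEPSWeightParams
    rmse: float
    n_iter: int
    converged: bool
    residuals: np.ndarray
    rmse_initial: float
    flags: tuple = ()


@dataclass
class FittedSubject:
    """A subject with fitted curves and derived landmarks."""

    subject_id: str
    sex: str
    ga_weeks: float
    height_params: QEPSHeightParams
    weight_params: Optional[QEPSWeightParams] = None
    whf: float = 0.0
    landmarks: Optional[PubertyLandmarks] = None
    height_rmse: float = float("nan")
    weight_rmse: float = float("nan")
    converged: bool = True
    flags: tuple = ()

    @property
    def age_p5(self) -> float:
        return self.landmarks.age_p5 if self.landmarks else float("nan")

    def curve(self, variable: str) -> GrowthCurve:
        kind = {"height": "height", "weight": "sqrt_weight", "bmi": "sqrt_bmi"}[variable]
        return GrowthCurve(kind=kind, height_params=self.height_params,
                           weight_params=self.weight_params)


# ---------------------------------------------------------------------------
# variable-projection least squares
# ---------------------------------------------------------------------------

# shape vector: [kE, TQ, thetaP, bP, dS, bS] with thetaS = thetaP + dS
_LOWER = np.array([0.2, 14.0, 7.0, 0.25, 0.5, 0.25])
_UPPER = np.array([4.0, 26.0, 18.0, 2.5, 8.0, 2.5])
_XSCALE = np.array([0.3, 2.0, 1.0, 0.3, 1.0, 0.3])


def _shape_from_vec(x: np.ndarray, t0: float = DEFAULT_T0) -> QEPSShape:
    kE, TQ, thetaP, bP, dS, bS = x
    return QEPSShape(kE=kE, TQ=TQ, thetaP=thetaP, bP=bP,
                     thetaS=thetaP + dS, bS=bS, t0=t0)


def _design(shape: QEPSShape, t: np.ndarray) -> np.ndarray:
    sq, se = _stop_loss_units(shape, t)
    return np.column_stack([_q_u(t, shape) - sq, _e_u(t, shape) - se,
                            _p_u(t, shape)])


def _profile_amplitudes(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    amp, *_ = np.linalg.lstsq(A, y, rcond=None)
    if np.any(amp < 0):
        amp, _ = nnls(A, y)
    return amp


def _initial_shape_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Heuristic start: pubertal midpoint near the steepest 3-point velocity."""
    theta0 = 12.0
    mask = (t >= 6.0) & (t <= 19.0)
    if mask.sum() >= 3:
        ts, ys = t[mask], y[mask]
        v = (ys[2:] - ys[:-2]) / (ts[2:] - ts[:-2])
        theta0 = float(np.clip(ts[1:-1][np.argmax(v)] + 0.2, 8.0, 16.0))
    return np.array([1.45, 19.5, theta0, 0.7, 2.2, 1.1])


def _jitter_start(x0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    x = x0 * np.exp(rng.normal(0, [0.15, 0.04, 0.0, 0.2, 0.15, 0.2]))
    x[2] = x0[2] + rng.normal(0, 0.8)
    return np.clip(x, _LOWER + 1e-9, _UPPER - 1e-9)


def _fit_varpro(t: np.ndarray, y: np.ndarray, x0: np.ndarray, seed: int,
                penalty=None,
                n_starts: int = N_MULTISTARTS) -> tuple[np.ndarray, np.ndarray, dict]:
    """Multi-start bounded VarPro fit; returns (shape vec, amplitudes, info).

    ``penalty`` is one (sqrt-weights, targets) pair over the shape vector,
    or a list of such pairs, appended as extra ridge residuals (used for the
    height-informed weight fit and the cohort empirical-Bayes pass).
    """
    penalties = [] if penalty is None else (
        [penalty] if isinstance(penalty, tuple) else list(penalty))

    def residual(x):
        A = _design(_shape_from_vec(x), t)
        amp = _profile_amplitudes(A, y)
        r = A @ amp - y
        for w, target in penalties:
            r = np.concatenate([r, w * (x - target)])
        return r

    rng = np.random.default_rng(seed)
    starts = [x0] + [_jitter_start(x0, rng) for _ in range(n_starts - 1)]
    best = None
    n_iter = 0
    for x_start in starts:
        res = least_squares(residual, x_start, bounds=(_LOWER, _UPPER),
                            x_scale=_XSCALE, method="trf",
                            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=400)
        n_iter += res.nfev
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-12 * max(1.0, t.size):   # essentially perfect fit
            break
    A = _design(_shape_from_vec(best.x), t)
    amp = _profile_amplitudes(A, y)
    data_res = A @ amp - y
    r0 = _design(_shape_from_vec(x0), t)
    amp0 = _profile_amplitudes(r0, y)
    info = dict(
        n_iter=n_iter,
        converged=bool(best.success and np.all(np.isfinite(best.x))),
        residuals=data_res,
        rmse=float(np.sqrt(np.mean(data_res ** 2))),
        rmse_initial=float(np.sqrt(np.mean((r0 @ amp0 - y) ** 2))),
    )
    return best.x, amp, info


def _information_flags(t: np.ndarray, n_min: int = 8) -> tuple:
    flags = []
    if t.size < n_min or t.min() > 3.0 or t.max() < 15.0:
        flags.append("low_information")
    return tuple(flags)


#: prior SDs (same units as the shape vector) used by the cohort-level
#: empirical-Bayes second pass, sized to the plausible inter-individual
#: spread of each shape parameter; penalty weights scale with the estimated
#: residual noise, so the shrinkage vanishes on noise-free data
SHAPE_PRIOR_SD = {0: 0.05, 1: 0.4, 3: 0.06, 4: 0.15, 5: 0.10}  # kE, TQ, bP, dS, bS

#: prior centres for the stop phase (dS = thetaS - thetaP, and bS): these are
#: too weakly identified per subject for a data-driven centre, so they are
#: fixed at field-typical maturation tempo - basic growth stops a couple of
#: years after the pubertal midpoint, over about a year's width (weight a
#: little later, as weight keeps accruing after height growth ends)
STOP_PRIOR_CENTER = {"height": (2.2, 1.1), "weight": (2.4, 1.0)}

_SHARED_IDX = np.array([0, 1, 3, 4, 5])   # all shape params except thetaP


def _shrinkage_penalty(targets: np.ndarray, noise_scale: float,
                       ) -> tuple[np.ndarray, np.ndarray]:
    w = np.zeros(6)
    for j, psd in SHAPE_PRIOR_SD.items():
        w[j] = noise_scale / psd
    return w, targets


def _pooled_shape(series: list, theta_p: list, x_init: np.ndarray) -> np.ndarray:
    """Cohort-pooled estimate of the shared shape parameters.

    Fits one (kE, TQ, bP, dS, bS) vector jointly to every subject's series,
    holding each subject's pubertal midpoint at its per-subject estimate and
    profiling each subject's amplitudes.  Individual shape deviations
    average out, giving a far better population centre for the weakly
    identified parameters than the median of per-subject fits (which
    overfit the stop width toward its bound).
    """

    from scipy.sparse import lil_matrix

    n = len(series)
    sizes = [t.size for t, _ in series]

    def resid(z):
        rs = []
        for i, (t, y) in enumerate(series):
            x = np.array([z[0], z[1], z[5 + i], z[2], z[3], z[4]])
            A = _design(_shape_from_vec(x), t)
            amp = _profile_amplitudes(A, y)
            rs.append(A @ amp - y)
        return np.concatenate(rs)

    # each subject's residual block depends on the shared params and its own
    # pubertal midpoint only; the grouped finite-difference jacobian then
    # costs O(shared) evaluations instead of O(n)
    sparsity = lil_matrix((sum(sizes), 5 + n), dtype=int)
    row = 0
    for i, m in enumerate(sizes):
        sparsity[row:row + m, :5] = 1
        sparsity[row:row + m, 5 + i] = 1
        row += m
    z0 = np.concatenate([x_init, theta_p])
    lb = np.concatenate([_LOWER[_SHARED_IDX], np.full(n, _LOWER[2])])
    ub = np.concatenate([_UPPER[_SHARED_IDX], np.full(n, _UPPER[2])])
    res = least_squares(resid, np.clip(z0, lb + 1e-9, ub - 1e-9),
                        bounds=(lb, ub), jac_sparsity=sparsity,
                        x_scale=np.concatenate([_XSCALE[_SHARED_IDX],
                                                np.ones(n)]),
                        max_nfev=120)
    full = np.empty(6)
    full[_SHARED_IDX] = res.x[:5]
    full[2] = float(np.median(res.x[5:]))
    return full


def fit_height(subject: Subject, seed: int = 0,
               n_starts: int = N_MULTISTARTS,
               penalty: Optional[tuple[np.ndarray, np.ndarray]] = None,
               x0: Optional[np.ndarray] = None) -> FitResult:
    """Fit QEPS height parameters to a subject's height series.

    Refuses with < 4 height points; fits with < 8 points or without
    infancy-to-adolescence coverage are flagged ``low_information``.  A
    fitted P amplitude below the spurt threshold is flagged ``no_spurt``.
    ``penalty`` optionally adds ridge residuals over the shape vector (used
    by the cohort pipeline's empirical-Bayes pass).
    """
    t, y = subject.series("height")
    if t.size < 4:
        raise ValueError(
            f"subject {subject.id}: {t.size} height points; at least 4 required")
    if x0 is None:
        x0 = _initial_shape_guess(t, y)
    x, amp, info = _fit_varpro(t, y, x0, seed, penalty=penalty, n_starts=n_starts)
    params = QEPSHeightParams(hQ=amp[0], hE=amp[1], hP=amp[2],
                              shape=_shape_from_vec(x))
    flags = _information_flags(t)
    lm = puberty_landmarks(params)
    if not lm.has_spurt:
        flags = flags + ("no_spurt",)
    return FitResult(params=params, rmse=info["rmse"], n_iter=info["n_iter"],
                     converged=info["converged"], residuals=info["residuals"],
                     rmse_initial=info["rmse_initial"], flags=flags)


_TIMING_IDX = np.array([2, 3, 4, 5])      # thetaP, bP, dS, bS in the shape vector


def fit_weight(subject: Subject, height_fit: FitResult, seed: int = 0,
               lam: float = DEFAULT_WEIGHT_TIMING_LAMBDA,
               n_starts: int = N_MULTISTARTS,
               extra_penalty: Optional[tuple[np.ndarray, np.ndarray]] = None,
               x0: Optional[np.ndarray] = None) -> FitResult:
    """Fit QEPS weight parameters on the kg^0.5 scale.

    The shape search starts at the fitted height shape and the pubertal
    timing parameters (thetaP, bP, thetaS, bS) are shrunk toward it by a
    ridge penalty of weight ``lam``; amplitudes are free.  Residuals and
    rmse are on the kg^0.5 scale.
    """
    if not height_fit.converged:
        raise ValueError(f"subject {subject.id}: height fit did not converge")
    t, w = subject.series("weight")
    if t.size < 4:
        raise ValueError(
            f"subject {subject.id}: {t.size} weight points; at least 4 required")
    y = np.sqrt(w)
    hs = height_fit.params.shape
    h_vec = np.clip(np.array([hs.kE, hs.TQ, hs.thetaP, hs.bP,
                              hs.thetaS - hs.thetaP, hs.bS]),
                    _LOWER + 1e-9, _UPPER - 1e-9)
    if x0 is None:
        x0 = h_vec
    weights = np.zeros(6)
    weights[_TIMING_IDX] = np.sqrt(lam)
    penalties = [(weights, h_vec.copy())]
    if extra_penalty is not None:
        penalties.append(extra_penalty)
    x, amp, info = _fit_varpro(t, y, x0, seed, penalty=penalties,
                               n_starts=n_starts)
    params = QEPSWeightParams(wQ=amp[0], wE=amp[1], wP=amp[2],
                              shape=_shape_from_vec(x), whf=0.0)
    return FitResult(params=params, rmse=info["rmse"], n_iter=info["n_iter"],
                     converged=info["converged"], residuals=info["residuals"],
                     rmse_initial=info["rmse_initial"], flags=_information_flags(t))


# ---------------------------------------------------------------------------
# cohort-level WHF estimation
# ---------------------------------------------------------------------------

WHF_AGE_GRID = np.arange(2.0, 18.0 + 1e-9, 0.25)
MIN_WHF_COHORT = 30


@dataclass
class WhfModel:
    """Per-sex linear maps from height amplitudes to typical weight amplitudes.

    ``coef[sex]`` is a (4, 3) matrix mapping [1, hQ, hE, hP] to
    (wQ, wE, wP), rescaled so the cohort-mean curve ratio is exactly 1 -
    hence cohort-mean WHF is exactly 0.
    """

    coef: dict
    age_grid: np.ndarray = field(default_factory=lambda: WHF_AGE_GRID.copy())


def predict_weight_amplitudes(model: WhfModel, sex: str,
                              hparams: QEPSHeightParams) -> np.ndarray:
    x = np.array([1.0, hparams.hQ, hparams.hE, hparams.hP])
    return np.maximum(x @ model.coef[sex], 1e-6)


def _sqrt_weight_curve(amps: np.ndarray, shape: QEPSShape, t: np.ndarray) -> np.ndarray:
    return _design(shape, t) @ amps


def whf_for(model: WhfModel, sex: str, hparams: QEPSHeightParams,
            wparams: QEPSWeightParams) -> float:
    """WHF of one subject: mean own/typical sqrt-weight curve ratio minus 1.

    The typical curve uses the cohort-predicted amplitudes with the
    subject's own fitted weight shape, so a subject lying exactly on the
    typical relation has WHF = 0 identically.
    """
    amps_own = np.asarray(wparams.amplitudes, float) * (1.0 + wparams.whf)
    amps_typ = predict_weight_amplitudes(model, sex, hparams)
    t = model.age_grid
    own = _sqrt_weight_curve(amps_own, wparams.shape, t)
    typ = _sqrt_weight_curve(amps_typ, wparams.shape, t)
    return float(np.mean(own / typ) - 1.0)


def estimate_whf(subjects: Sequence[FittedSubject]) -> WhfModel:
    """Estimate the typical weight-from-height relation and per-subject WHF.

    Requires >= 30 converged height/weight pairs per sex present in the
    cohort.  Subjects are updated in place: ``whf`` is set and the weight
    amplitudes are renormalised by (1 + whf) so the weight curve itself is
    unchanged.  Cohort-mean WHF is exactly zero per sex by construction.
    """
    coef = {}
    for sex in ("F", "M"):
        grp = [s for s in subjects
               if s.sex == sex and s.weight_params is not None and s.converged]
        if not grp:
            continue
        if len(grp) < MIN_WHF_COHORT:
            raise ValueError(
                f"need >= {MIN_WHF_COHORT} converged height/weight pairs for sex "
                f"{sex}, got {len(grp)}")
        X = np.array([[1.0, s.height_params.hQ, s.height_params.hE,
                       s.height_params.hP] for s in grp])
        Y = np.array([np.asarray(s.weight_params.amplitudes)
                      * (1.0 + s.weight_params.whf) for s in grp])
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        model_sex = WhfModel(coef={sex: B})
        ratios = np.array([whf_for(model_sex, sex, s.height_params,
                                   s.weight_params) + 1.0 for s in grp])
        coef[sex] = B * float(np.mean(ratios))
    if not coef:
        raise ValueError("no converged height/weight pairs in cohort")
    model = WhfModel(coef=coef)
    for s in subjects:
        if s.sex in coef and s.weight_params is not None and s.converged:
            w = whf_for(model, s.sex, s.height_params, s.weight_params)
            wp = s.weight_params
            scale = (1.0 + wp.whf) / (1.0 + w)
            s.weight_params = QEPSWeightParams(
                wQ=wp.wQ * scale, wE=wp.wE * scale, wP=wp.wP * scale,
                shape=wp.shape, whf=w)
            s.whf = w
    return model


# ---------------------------------------------------------------------------
# pipeline and cohort cleaning
# ---------------------------------------------------------------------------

def _shape_vec(shape: QEPSShape) -> np.ndarray:
    return np.array([shape.kE, shape.TQ, shape.thetaP, shape.bP,
                     shape.thetaS - shape.thetaP, shape.bS])


def _subject_seed(seed: int, subject_id: str) -> int:
    digest = sum((i + 1) * ord(c) for i, c in enumerate(subject_id)) % 2**31
    return int(np.random.default_rng([seed, digest]).integers(2**31))


def fit_cohort(subjects: Iterable[Subject], seed: int = 0,
               fit_weights: bool = True,
               n_starts: int = N_MULTISTARTS,
               shrinkage: bool = True) -> list[FittedSubject]:
    """Fit a whole cohort and derive landmarks and WHF.

    Two passes per variable.  Pass 1 fits every subject independently.
    Pass 2 (``shrinkage=True``) refits with an empirical-Bayes ridge that
    pulls the weakly identified shape parameters (kE, TQ, bP, dS, bS)
    toward the per-sex cohort medians from pass 1, with penalty weights
    proportional to the cohort's median residual noise - so the penalty
    disappears for noise-free data and never touches the individual
    pubertal timing ``thetaP``.  Deterministic given ``seed``.
    """
    subjects = list(subjects)
    fitted: list[FittedSubject] = []
    hfits: dict[str, FitResult] = {}
    wfits: dict[str, Optional[FitResult]] = {}
    for subject in subjects:
        sub_seed = _subject_seed(seed, subject.id)
        hfit = fit_height(subject, seed=sub_seed, n_starts=n_starts)
        hfits[subject.id] = hfit
        wfit = None
        if fit_weights and subject.series("weight")[0].size >= 4 and hfit.converged:
            wfit = fit_weight(subject, hfit, seed=sub_seed, n_starts=n_starts)
        wfits[subject.id] = wfit

    if shrinkage:
        for sex in ("F", "M"):
            grp = [s for s in subjects if s.sex == sex and hfits[s.id].converged]
            if len(grp) < MIN_WHF_COHORT:
                continue
            h_med = np.median([_shape_vec(hfits[s.id].params.shape) for s in grp],
                              axis=0)
            # neutral stop-width start keeps the pooled fit off the bound
            h_pool = _pooled_shape(
                [s.series("height") for s in grp],
                [hfits[s.id].params.shape.thetaP for s in grp],
                np.array([h_med[0], h_med[1], h_med[3], h_med[4], 1.0]))
            h_pool[4], h_pool[5] = STOP_PRIOR_CENTER["height"]
            h_noise = float(np.median([hfits[s.id].rmse for s in grp]))
            h_pen = _shrinkage_penalty(h_pool, h_noise)
            wgrp = [s for s in grp if wfits[s.id] is not None]
            if wgrp:
                w_med = np.median([_shape_vec(wfits[s.id].params.shape)
                                   for s in wgrp], axis=0)
                w_pool = _pooled_shape(
                    [(s.series("weight")[0], np.sqrt(s.series("weight")[1]))
                     for s in wgrp],
                    [wfits[s.id].params.shape.thetaP for s in wgrp],
                    np.array([w_med[0], w_med[1], w_med[3], w_med[4], 1.0]))
                w_pool[4], w_pool[5] = STOP_PRIOR_CENTER["weight"]
                w_noise = float(np.median([wfits[s.id].rmse for s in wgrp]))
                w_pen = _shrinkage_penalty(w_pool, w_noise)
            for s in grp:
                sub_seed = _subject_seed(seed, s.id)
                hfits[s.id] = fit_height(
                    s, seed=sub_seed, n_starts=1, penalty=h_pen,
                    x0=np.clip(_shape_vec(hfits[s.id].params.shape),
                               _LOWER + 1e-9, _UPPER - 1e-9))
                if wfits[s.id] is not None:
                    wfits[s.id] = fit_weight(
                        s, hfits[s.id], seed=sub_seed, n_starts=1,
                        extra_penalty=w_pen,
                        x0=np.clip(_shape_vec(wfits[s.id].params.shape),
                                   _LOWER + 1e-9, _UPPER - 1e-9))

    for subject in subjects:
        hfit, wfit = hfits[subject.id], wfits[subject.id]
        fitted.append(FittedSubject(
            subject_id=subject.id, sex=subject.sex, ga_weeks=subject.ga_weeks,
            height_params=hfit.params,
            weight_params=wfit.params if wfit else None,
            landmarks=puberty_landmarks(hfit.params),
            height_rmse=hfit.rmse,
            weight_rmse=wfit.rmse if wfit else float("nan"),
            converged=hfit.converged and (wfit is None or wfit.converged),
            flags=hfit.flags + (wfit.flags if wfit else ())))
    if fit_weights and any(s.weight_params is not None for s in fitted):
        try:
            estimate_whf(fitted)
        except ValueError:
            pass   # cohort too small for a stable typical relation
    return fitted


DEFAULT_BMI_SDS_CUTOFF = 2.5
_CHILDHOOD_BMI_WINDOW = {"F": (3.5, 7.0), "M": (3.5, 8.0)}


def clean_reference_cohort(subjects: Sequence[FittedSubject],
                           bmi_sds_cutoff: float = DEFAULT_BMI_SDS_CUTOFF,
                           ) -> tuple[list[FittedSubject], pd.DataFrame]:
    """Apply reference-population cleaning: term birth plus a severe-obesity
    filter against a provisional internal BMI reference.

    A subject is excluded when GA lies outside 37-43 weeks, or when the
    maximum BMI SDS of its fitted curve over the sex-specific childhood
    window exceeds ``bmi_sds_cutoff``.  Returns the kept subjects and an
    exclusion log with one row per exclusion and its trigger.
    """
    from . import references  # local import; references is downstream of core only

    log = []
    eligible = []
    for s in subjects:
        if not GA_TERM_RANGE[0] <= s.ga_weeks <= GA_TERM_RANGE[1]:
            log.append(dict(subject_id=s.subject_id, reason="ga_ineligible",
                            detail=f"ga_weeks={s.ga_weeks:g}"))
        else:
            eligible.append(s)

    kept = []
    for sex in ("F", "M"):
        grp = [s for s in eligible
               if s.sex == sex and s.weight_params is not None]
        others = [s for s in eligible
                  if s.sex == sex and s.weight_params is None]
        kept.extend(others)   # no BMI curve: term-eligibility only
        if not grp:
            continue
        ref = references.build_reference(
            grp, sex=sex, variable="bmi", component="total", axis="cage",
            min_subjects=min(30, len(grp)))
        lo, hi = _CHILDHOOD_BMI_WINDOW[sex]
        ages = np.arange(lo, hi + 1e-9, 0.1)
        for s in grp:
            vals = s.curve("bmi").value(ages)
            sds = references.sds_lookup(ref, ages, vals)
            worst = float(np.max(sds))
            if worst > bmi_sds_cutoff:
                log.append(dict(subject_id=s.subject_id,
                                reason="childhood_bmi_sds",
                                detail=f"max_sds={worst:.2f}"))
            else:
                kept.append(s)
    if not kept:
        import warnings
        warnings.warn("cohort cleaning removed every subject")
    kept.sort(key=lambda s: s.subject_id)
    return kept, pd.DataFrame(log, columns=["subject_id", "reason", "detail"])


# ---------------------------------------------------------------------------
# flat per-subject records (CSV interchange)
# ---------------------------------------------------------------------------

_H_SHAPE_COLS = ("h_kE", "h_TQ", "h_thetaP", "h_bP", "h_thetaS", "h_bS", "h_t0")
_W_SHAPE_COLS = ("w_kE", "w_TQ", "w_thetaP", "w_bP", "w_thetaS", "w_bS", "w_t0")
_SHAPE_FIELDS = ("kE", "TQ", "thetaP", "bP", "thetaS", "bS", "t0")


def fitted_to_frame(subjects: Sequence[FittedSubject]) -> pd.DataFrame:
    """Flatten fitted subjects to one record per subject."""
    rows = []
    for s in subjects:
        rec = dict(subject_id=s.subject_id, sex=s.sex, ga_weeks=s.ga_weeks,
                   hQ=s.height_params.hQ, hE=s.height_params.hE,
                   hP=s.height_params.hP)
        rec.update({c: getattr(s.height_params.shape, f)
                    for c, f in zip(_H_SHAPE_COLS, _SHAPE_FIELDS)})
        if s.weight_params is not None:
            rec.update(wQ=s.weight_params.wQ, wE=s.weight_params.wE,
                       wP=s.weight_params.wP, whf=s.weight_params.whf)
            rec.update({c: getattr(s.weight_params.shape, f)
                        for c, f in zip(_W_SHAPE_COLS, _SHAPE_FIELDS)})
        lm = s.landmarks
        rec.update(age_p5=lm.age_p5 if lm else np.nan,
                   age_p50=lm.age_p50 if lm else np.nan,
                   age_tphv=lm.age_tphv if lm else np.nan,
                   height_rmse=s.height_rmse, weight_rmse=s.weight_rmse,
                   converged=s.converged, flags=";".join(s.flags))
        rows.append(rec)
    return pd.DataFrame(rows)


def fitted_from_frame(df: pd.DataFrame) -> list[FittedSubject]:
    """Rebuild FittedSubject objects from a flat record table."""
    out = []
    for _, r in df.iterrows():
        hshape = QEPSShape(**{f: float(r[c])
                              for c, f in zip(_H_SHAPE_COLS, _SHAPE_FIELDS)})
        hparams = QEPSHeightParams(float(r["hQ"]), float(r["hE"]),
                                   float(r["hP"]), hshape)
        wparams = None
        if "wQ" in r and pd.notna(r.get("wQ")):
            wshape = QEPSShape(**{f: float(r[c])
                                  for c, f in zip(_W_SHAPE_COLS, _SHAPE_FIELDS)})
            wparams = QEPSWeightParams(float(r["wQ"]), float(r["wE"]),
                                       float(r["wP"]), wshape,
                                       whf=float(r.get("whf", 0.0)))
        lm = None
        if pd.notna(r.get("age_p5")):
            lm = PubertyLandmarks(age_p5=float(r["age_p5"]),
                                  age_p50=float(r["age_p50"]),
                                  age_tphv=float(r["age_tphv"]))
        flags = tuple(str(r.get("flags", "")).split(";")) if r.get("flags") else ()
        out.append(FittedSubject(
            subject_id=str(r["subject_id"]), sex=str(r["sex"]),
            ga_weeks=float(r["ga_weeks"]), height_params=hparams,
            weight_params=wparams,
            whf=float(r.get("whf", 0.0)) if pd.notna(r.get("whf", np.nan)) else 0.0,
            landmarks=lm,
            height_rmse=float(r.get("height_rmse", np.nan)),
            weight_rmse=float(r.get("weight_rmse", np.nan)),
            converged=bool(r.get("converged", True)), flags=flags))
    return out
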