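"""Core QEPS growth-function family.

The QEPS model describes an individual's growth (height in cm, weight on the
square-root scale in kg^0.5) as the sum of four bounded component functions of
gestational-age-corrected age ``t`` (years, t = 0 at a 40-week term birth):

* ``Q`` - a quadratic component rising from conception and reaching a plateau
  at age ``TQ`` post-conception; together with
* ``E`` - an exponential component saturating during infancy, it forms the
  basic / prepubertal growth ``QE``;
* ``P`` - a specific pubertal component, a logistic step centred at
  ``thetaP`` with width ``bP`` whose amplitude is the total pubertal gain
  (``Pmax``);
* ``S`` - a stop component that terminates basic growth at maturity: the
  basic velocity is damped by a logistic sigmoid centred at ``thetaS``,
  yielding the basic-during-puberty curve ``QES``.

Total growth is ``QE + P - S`` which, with ``S := QE - QES``, is identically
``QES + P`` (additivity).  BMI lives on the ``kg^0.5/m`` scale: the square
root of weight divided by height in metres, so that conventional BMI (kg/m^2)
is the square of the model value.

All functions accept scalars or numpy arrays for the age argument.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = [
    "DEFAULT_T0",
    "AGE_MAX",
    "COMPONENTS",
    "DomainError",
    "QEPSShape",
    "QEPSHeightParams",
    "QEPSWeightParams",
    "PubertyLandmarks",
    "GrowthCurve",
    "unit_function",
    "curve_value",
    "velocity",
    "age_at_p_fraction",
    "age_at_peak_velocity",
    "puberty_landmarks",
    "bmi_curve_value",
    "bmi_to_conventional",
]

#: years from conception to a 40-gestational-week term birth
DEFAULT_T0 = 40 * 7 / 365.25

#: oldest age (years) at which curves are defined
AGE_MAX = 30.0

COMPONENTS = ("total", "Q", "E", "P", "S", "QE", "QES")

_GL_NODES, _GL_WEIGHTS = leggauss(8)
_PANEL = 0.25  # max quadrature panel width (y)


class DomainError(ValueError):
    """Raised when a curve is evaluated outside its age domain."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QEPSShape:
    """Timing/shape parameters shared by the four component functions.

    Parameters
    ----------
    kE : exponential saturation rate (1/y).
    TQ : age post-conception at which the quadratic plateaus (y).
    thetaP : pubertal logistic midpoint (y, GA-corrected age).
    bP : pubertal logistic width (y).
    thetaS : stop-sigmoid midpoint (y); must exceed ``thetaP``.
    bS : stop-sigmoid width (y).
    t0 : conception-to-birth offset (y); default 40 gestational weeks.
    """

    kE: float
    TQ: float
    thetaP: float
    bP: float
    thetaS: float
    bS: float
    t0: float = DEFAULT_T0

    def __post_init__(self) -> None:
        for name in ("kE", "TQ", "thetaP", "bP", "thetaS", "bS", "t0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"QEPSShape.{name} must be finite and > 0, got {v!r}")
        if not self.thetaP < self.thetaS:
            raise ValueError(
                f"stop midpoint thetaS={self.thetaS} must lie after pubertal "
                f"midpoint thetaP={self.thetaP}"
            )
        if self.bP >= 5 or self.bS >= 5:
            raise ValueError("component widths bP, bS must be < 5 y")


@dataclass(frozen=True)
class QEPSHeightParams:
    """Per-individual height parameters: amplitudes (cm) plus shape.

    ``hP`` equals Pmax, the total puberty-specific height gain.
    """

    hQ: float
    hE: float
    hP: float
    shape: QEPSShape

    def __post_init__(self) -> None:
        for name in ("hQ", "hE", "hP"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        return (self.hQ, self.hE, self.hP)

    @property
    def pmax(self) -> float:
        return self.hP


@dataclass(frozen=True)
class QEPSWeightParams:
    """Per-individual weight parameters on the kg^0.5 scale.

    The whole curve is scaled by ``(1 + whf)`` where ``whf`` is the
    constitutional weight-height factor (0 = normal, > 0 heavy, < 0 lean).
    Weight has its own shape: pubertal weight timing may differ from height.
    """

    wQ: float
    wE: float
    wP: float
    shape: QEPSShape
    whf: float = 0.0

    def __post_init__(self) -> None:
        for name in ("wQ", "wE", "wP"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not np.isfinite(self.whf):
            raise ValueError("whf must be finite")

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        return (self.wQ, self.wE, self.wP)


@dataclass(frozen=True)
class PubertyLandmarks:
    """Derived pubertal landmarks of a fitted height curve.

    ``age_p5`` is the operational onset of puberty: the age at which 5% of the
    total P-function gain (Pmax) has been attained.  ``age_tphv`` is the age
    at peak height velocity of the total curve.
    """

    age_p5: float
    age_p50: float
    age_tphv: float
    has_spurt: bool = True
    height_sds_at_onset: Optional[float] = None


# ---------------------------------------------------------------------------
# unit functions (amplitude-free, values in [0, 1])
# ---------------------------------------------------------------------------

def _check_domain(t: np.ndarray, t0: float) -> None:
    if np.any(t < -t0 - 1e-12):
        raise DomainError(f"age {np.min(t)} y precedes conception (-t0 = {-t0} y)")


def _q_u(t, sh: QEPSShape):
    s = np.clip((np.asarray(t, float) + sh.t0) / sh.TQ, 0.0, 1.0)
    return s * (2.0 - s)


def _q_du(t, sh: QEPSShape):
    t = np.asarray(t, float)
    s = (t + sh.t0) / sh.TQ
    return np.where((s >= 0.0) & (s < 1.0), 2.0 * (1.0 - np.clip(s, 0.0, 1.0)) / sh.TQ, 0.0)


def _e_u(t, sh: QEPSShape):
    return -np.expm1(-sh.kE * (np.asarray(t, float) + sh.t0))


def _e_du(t, sh: QEPSShape):
    return sh.kE * np.exp(-sh.kE * (np.asarray(t, float) + sh.t0))


def _p_u(t, sh: QEPSShape):
    return expit((np.asarray(t, float) - sh.thetaP) / sh.bP)


def _p_du(t, sh: QEPSShape):
    p = _p_u(t, sh)
    return p * (1.0 - p) / sh.bP


def _sigma_s(t, sh: QEPSShape):
    return expit((np.asarray(t, float) - sh.thetaS) / sh.bS)


def _sigma_ds(t, sh: QEPSShape):
    s = _sigma_s(t, sh)
    return s * (1.0 - s) / sh.bS


_UNIT = {"Q": _q_u, "E": _e_u, "P": _p_u, "stop_sigma": _sigma_s}


def unit_function(kind: str, t, shape: QEPSShape):
    """Evaluate a unit component function (range [0, 1]) at age ``t``.

    ``kind`` is one of ``Q``, ``E``, ``P`` or ``stop_sigma``.  Ages before
    conception (t < -t0) raise :class:`DomainError`.
    """
    if kind not in _UNIT:
        raise ValueError(f"unknown unit function {kind!r}; expected one of {sorted(_UNIT)}")
    arr = np.asarray(t, float)
    _check_domain(arr, shape.t0)
    out = _UNIT[kind](arr, shape)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# stop-loss integral (the S component per unit amplitude)
# ---------------------------------------------------------------------------

def _stop_loss_units(shape: QEPSShape, ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit stop losses ``SQ(t) = int_{-t0}^t sigma_S dQ_u`` and likewise SE.

    Composite Gauss-Legendre quadrature on panels no wider than ``_PANEL`` y;
    panel edges include every requested age and the Q-plateau kink, so the
    result is exact to near machine precision for these smooth integrands.
    """
    ts = np.asarray(ts, float)
    flat = np.ravel(ts)
    sq = np.zeros_like(flat)
    se = np.zeros_like(flat)
    # below lo the stop sigmoid is < ~1e-18: the integral is numerically zero
    lo = max(-shape.t0, shape.thetaS - 42.0 * shape.bS)
    hi = float(np.max(flat, initial=lo))
    active = flat > lo
    if hi > lo and np.any(active):
        edges = [np.arange(lo, hi, _PANEL), [hi], flat[active]]
        kink = shape.TQ - shape.t0
        if lo < kink < hi:
            edges.append([kink])
        e = np.unique(np.concatenate([np.asarray(x, float) for x in edges]))
        mid = 0.5 * (e[1:] + e[:-1])
        half = 0.5 * (e[1:] - e[:-1])
        nodes = mid[:, None] + half[:, None] * _GL_NODES[None, :]
        w = half[:, None] * _GL_WEIGHTS[None, :]
        sig = _sigma_s(nodes, shape)
        panel_q = np.sum(w * sig * _q_du(nodes, shape), axis=1)
        panel_e = np.sum(w * sig * _e_du(nodes, shape), axis=1)
        cum_q = np.concatenate([[0.0], np.cumsum(panel_q)])
        cum_e = np.concatenate([[0.0], np.cumsum(panel_e)])
        idx = np.searchsorted(e, flat[active])
        sq[active] = cum_q[idx]
        se[active] = cum_e[idx]
    return sq.reshape(ts.shape), se.reshape(ts.shape)


# ---------------------------------------------------------------------------
# scaled component curves and velocities
# ---------------------------------------------------------------------------

def _amps_scale(params) -> tuple[float, float, float, float, QEPSShape]:
    if isinstance(params, QEPSHeightParams):
        return params.hQ, params.hE, params.hP, 1.0, params.shape
    if isinstance(params, QEPSWeightParams):
        return params.wQ, params.wE, params.wP, 1.0 + params.whf, params.shape
    raise TypeError(f"expected QEPSHeightParams or QEPSWeightParams, got {type(params)!r}")


def curve_value(params, t, component: str = "total"):
    """Evaluate a component of the growth curve at GA-corrected age ``t``.

    Height params give cm; weight params give kg^0.5 (scaled by 1 + whf).
    ``component`` is one of ``total, Q, E, P, S, QE, QES``; the identities
    ``total = QES + P = QE + P - S`` hold exactly by construction.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
    aQ, aE, aP, scale, sh = _amps_scale(params)
    arr = np.asarray(t, float)
    _check_domain(arr, sh.t0)
    if np.any(arr > AGE_MAX + 1e-9):
        raise DomainError(f"age {np.max(arr)} y beyond supported maximum {AGE_MAX} y")

    if component == "Q":
        out = aQ * _q_u(arr, sh)
    elif component == "E":
        out = aE * _e_u(arr, sh)
    elif component == "P":
        out = aP * _p_u(arr, sh)
    elif component == "QE":
        out = aQ * _q_u(arr, sh) + aE * _e_u(arr, sh)
    else:
        sq, se = _stop_loss_units(sh, arr)
        if component == "S":
            out = aQ * sq + aE * se
        elif component == "QES":
            out = aQ * (_q_u(arr, sh) - sq) + aE * (_e_u(arr, sh) - se)
        else:  # total
            out = (aQ * (_q_u(arr, sh) - sq) + aE * (_e_u(arr, sh) - se)
                   + aP * _p_u(arr, sh))
    out = scale * out
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def velocity(params, t, component: str = "total"):
    """Closed-form derivative (cm/y or kg^0.5/y) of :func:`curve_value`."""
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
    aQ, aE, aP, scale, sh = _amps_scale(params)
    arr = np.asarray(t, float)
    _check_domain(arr, sh.t0)

    if component == "Q":
        out = aQ * _q_du(arr, sh)
    elif component == "E":
        out = aE * _e_du(arr, sh)
    elif component == "P":
        out = aP * _p_du(arr, sh)
    elif component == "QE":
        out = aQ * _q_du(arr, sh) + aE * _e_du(arr, sh)
    else:
        basic = aQ * _q_du(arr, sh) + aE * _e_du(arr, sh)
        sig = _sigma_s(arr, sh)
        if component == "S":
            out = sig * basic
        elif component == "QES":
            out = (1.0 - sig) * basic
        else:  # total
            out = (1.0 - sig) * basic + aP * _p_du(arr, sh)
    out = scale * out
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# pubertal landmarks
# ---------------------------------------------------------------------------

def age_at_p_fraction(shape: QEPSShape, frac: float = 0.05) -> float:
    """Age at which the P-function has attained fraction ``frac`` of Pmax.

    The default ``frac = 0.05`` gives AgeP5, the operational onset of the
    pubertal growth spurt.  Closed-form logistic inverse:
    ``thetaP + bP * log(frac / (1 - frac))``.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must lie strictly in (0, 1), got {frac!r}")
    return shape.thetaP + shape.bP * math.log(frac / (1.0 - frac))


#: fitted P amplitudes below this (cm or kg^0.5) are treated as "no spurt"
MIN_SPURT_AMPLITUDE = 0.5


def age_at_peak_velocity(params, window: Optional[tuple[float, float]] = None) -> float:
    """Age at peak velocity of the total curve (AgeTPHV for height).

    Located by bounded scalar minimisation of the negated closed-form
    velocity on ``window`` (default ``[AgeP5 - 1, AgeP5 + 6]``) to 1e-6 y.
    Returns ``nan`` when the P amplitude is (near) zero - no spurt exists.
    """
    aP = _amps_scale(params)[2]
    if aP < MIN_SPURT_AMPLITUDE:
        return float("nan")
    if window is None:
        p5 = age_at_p_fraction(params.shape, 0.05)
        window = (p5 - 1.0, p5 + 6.0)
    lo = max(window[0], -params.shape.t0)
    hi = min(window[1], AGE_MAX)
    # coarse bracket first: the window maximum may sit at an edge when the
    # spurt is weak relative to decelerating basic growth
    grid = np.linspace(lo, hi, 256)
    k = int(np.argmax(velocity(params, grid, "total")))
    b_lo, b_hi = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda t: -velocity(params, t, "total"),
        bounds=(b_lo, b_hi), method="bounded",
        options={"xatol": 1e-6},
    )
    best = float(res.x)
    if velocity(params, grid[k], "total") > velocity(params, best, "total"):
        best = float(grid[k])
    return best


def puberty_landmarks(params: QEPSHeightParams) -> PubertyLandmarks:
    """Compute AgeP5, AgeP50 and AgeTPHV for a fitted height curve."""
    if params.hP < MIN_SPURT_AMPLITUDE:
        return PubertyLandmarks(float("nan"), float("nan"), float("nan"), has_spurt=False)
    return PubertyLandmarks(
        age_p5=age_at_p_fraction(params.shape, 0.05),
        age_p50=params.shape.thetaP,
        age_tphv=age_at_peak_velocity(params),
    )


# ---------------------------------------------------------------------------
# BMI on the kg^0.5/m scale
# ---------------------------------------------------------------------------

_BMI_COMPONENTS = ("total", "QE", "QES", "P")


def bmi_curve_value(hparams: QEPSHeightParams, wparams: QEPSWeightParams, t,
                    component: str = "total"):
    """QEPS-BMI at age ``t`` in kg^0.5/m (square root of weight over height).

    Being a ratio of curves, BMI components are not natively additive; the
    displayed decomposition is defined so that the shown pair does add up:

    * ``total`` - sqrt-weight total / height total (in m), exact;
    * ``QE``    - prepubertal: basic-only numerator over basic-only
      denominator without stop;
    * ``QES``   - basic BMI: QES weight over QES height;
    * ``P``     - puberty-specific BMI := total - QES (basic).

    Conventional BMI in kg/m^2 is the square of the returned value.
    """
    if component not in _BMI_COMPONENTS:
        raise ValueError(
            f"unknown BMI component {component!r}; expected one of {_BMI_COMPONENTS}")
    if component == "P":
        return (bmi_curve_value(hparams, wparams, t, "total")
                - bmi_curve_value(hparams, wparams, t, "QES"))
    comp = component
    h = curve_value(hparams, t, comp)
    w = curve_value(wparams, t, comp)
    h_m = np.asarray(h, float) / 100.0
    if np.any(h_m <= 0):
        raise ValueError(f"height must be positive to form BMI (component {comp})")
    out = np.asarray(w, float) / h_m
    return float(out) if np.isscalar(t) else out


def bmi_to_conventional(b):
    """Convert kg^0.5/m BMI to conventional kg/m^2 (squaring)."""
    return np.square(b)


# ---------------------------------------------------------------------------
# evaluable curve wrapper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCurve:
    """An evaluable fitted curve with component decomposition.

    ``kind`` is ``height``, ``sqrt_weight`` or ``sqrt_bmi``; BMI curves need
    both parameter sets.
    """

    kind: str
    height_params: Optional[QEPSHeightParams] = None
    weight_params: Optional[QEPSWeightParams] = None

    def __post_init__(self) -> None:
        if self.kind not in ("height", "sqrt_weight", "sqrt_bmi"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.kind in ("height", "sqrt_bmi") and self.height_params is None:
            raise ValueError(f"{self.kind} curve requires height_params")
        if self.kind in ("sqrt_weight", "sqrt_bmi") and self.weight_params is None:
            raise ValueError(f"{self.kind} curve requires weight_params")

    def value(self, t, component: str = "total"):
        if self.kind == "height":
            return curve_value(self.height_params, t, component)
        if self.kind == "sqrt_weight":
            return curve_value(self.weight_params, t, component)
        return bmi_curve_value(self.height_params, self.weight_params, t, component)

    def velocity(self, t, component: str = "total"):
        if self.kind == "height":
            return velocity(self.height_params, t, component)
        if self.kind == "sqrt_weight":
            return velocity(self.weight_params, t, component)
        # BMI velocity: central finite difference of the ratio curve
        h = 1e-5
        return (np.asarray(self.value(np.asarray(t) + h, component))
                - np.asarray(self.value(np.asarray(t) - h, component))) / (2 * h)
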