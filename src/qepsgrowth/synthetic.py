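"""Seeded synthetic longitudinal cohort generator.

Emulates, at the statistical level, a Scandinavian longitudinal growth
study: healthy term-born children (GA 37-43 weeks) measured from birth to
adult height on a child-health-surveillance visit schedule, with
QEPS-structured individual variation:

* a common *size factor* loading positively on height and (more strongly on)
  weight amplitudes - heavier builds for taller children, so basic BMI rises
  with stature while the puberty-specific amplitude loads only weakly,
  making relatively short children carry relatively more puberty-specific
  BMI;
* a shared pubertal *timing factor* (SD ~1.1 y) plus a systematic
  weight-before-height pubertal timing offset (default -0.5 y): the pubertal
  weight (fat-like) gain precedes the height spurt, which is what makes the
  aligned BMI references undulate around onset;
* a constitutional weight-height factor (WHF, mean 0) scaling the whole
  weight curve;
* measurement noise: height SD 0.4 cm, weight CV 1.5%.

Population means were calibrated once against Swedish-style growth
milestones (birth size, 1 y, 7 y, late-childhood and adult size) and are
frozen here; every distributional choice is exposed in
:class:`SyntheticCohortConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    QEPSShape,
    QEPSHeightParams,
    QEPSWeightParams,
    curve_value,
    puberty_landmarks,
)

__all__ = [
    "SyntheticCohortConfig",
    "DEFAULT_POPULATION",
    "sample_individual",
    "generate_cohort",
    "recovery_report",
]

#: per-sex population mean parameters (calibrated once, frozen)
DEFAULT_POPULATION = {
    "F": {
        "height": dict(hQ=89.570, hE=63.240, hP=20.949, kE=1.4809, TQ=19.0,
                       thetaP=11.7, bP=0.7, thetaS=13.7, bS=1.2),
        "weight": dict(wQ=4.0385, wE=2.4007, wP=1.7718, kE=1.4657, TQ=19.5,
                       bP=0.4, thetaS_minus_thetaP=2.2, bS=1.0),
    },
    "M": {
        "height": dict(hQ=91.032, hE=66.528, hP=26.826, kE=1.4216, TQ=20.0,
                       thetaP=13.7, bP=0.7, thetaS=15.7, bS=1.2),
        "weight": dict(wQ=4.4964, wE=2.4138, wP=1.7518, kE=1.5012, TQ=20.5,
                       bP=0.4, thetaS_minus_thetaP=2.2, bS=1.0),
    },
}

#: default visit schedule (postnatal years): infancy-dense, then annual
DEFAULT_SCHEDULE = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0) + tuple(
    float(a) for a in range(3, 20)) + (20.0,)


@dataclass
class SyntheticCohortConfig:
    """Population distributions, visit schedule and noise model.

    Loadings are relative (multiplicative) effects of the standard-normal
    common factors; SDs of the timing quantities are in years.
    """

    n: int = 1418
    n_female: int = 698
    population: dict = field(default_factory=lambda: {
        s: {k: dict(v) for k, v in DEFAULT_POPULATION[s].items()} for s in ("F", "M")})
    # common size factor loadings (relative per SD)
    height_amp_loading: float = 0.035
    weight_amp_loading: float = 0.055
    weight_p_loading: float = 0.015
    height_p_loading: float = 0.02
    # independent relative amplitude jitter
    height_amp_jitter: float = 0.012
    weight_amp_jitter: float = 0.02
    p_amp_jitter: float = 0.05
    # pubertal timing: shared factor SD and weight-vs-height systematic offset
    timing_sd: float = 1.1
    weight_timing_offset: float = -0.5
    weight_timing_jitter: float = 0.15
    stop_timing_jitter: float = 0.15
    width_jitter: float = 0.06       # lognormal sigma on bP, bS
    rate_jitter: float = 0.02        # lognormal sigma on kE, TQ
    whf_sd: float = 0.07
    # measurement noise
    height_noise_sd: float = 0.4     # cm
    weight_noise_cv: float = 0.015
    # gestational age (weeks): truncated normal on [37, 43]
    ga_mean: float = 40.0
    ga_sd: float = 1.2
    ga_range: tuple = (37.0, 43.0)
    schedule: tuple = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("height_amp_jitter", "weight_amp_jitter", "p_amp_jitter",
                     "timing_sd", "weight_timing_jitter", "stop_timing_jitter",
                     "width_jitter", "rate_jitter", "whf_sd",
                     "height_noise_sd", "weight_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.n_female <= self.n:
            raise ValueError("n_female must lie in [0, n]")
        if list(self.schedule) != sorted(self.schedule):
            raise ValueError("visit schedule ages must be increasing")


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def sample_individual(config: SyntheticCohortConfig, sex: str,
                      rng: np.random.Generator,
                      ) -> tuple[QEPSHeightParams, QEPSWeightParams, float]:
    """Draw one subject's true parameters: (height, weight, whf).

    Draws violating the shape invariants are rejection-resampled (bounded).
    """
    pop = config.population[sex]
    hmean, wmean = pop["height"], pop["weight"]
    for _ in range(100):
        g = rng.normal()          # common size factor
        tau = rng.normal(0.0, config.timing_sd)

        thetaP = hmean["thetaP"] + tau
        thetaS = hmean["thetaS"] + tau + rng.normal(0.0, config.stop_timing_jitter)
        shape_h = dict(
            kE=hmean["kE"] * np.exp(rng.normal(0, config.rate_jitter)),
            TQ=hmean["TQ"] * np.exp(rng.normal(0, config.rate_jitter)),
            thetaP=thetaP,
            bP=hmean["bP"] * np.exp(rng.normal(0, config.width_jitter)),
            thetaS=thetaS,
            bS=hmean["bS"] * np.exp(rng.normal(0, config.width_jitter)),
        )
        hQ = hmean["hQ"] * (1 + config.height_amp_loading * g
                            + rng.normal(0, config.height_amp_jitter))
        hE = hmean["hE"] * (1 + config.height_amp_loading * g
                            + rng.normal(0, config.height_amp_jitter))
        hP = hmean["hP"] * (1 + config.height_p_loading * g
                            + rng.normal(0, config.p_amp_jitter))

        thetaP_w = thetaP + config.weight_timing_offset + rng.normal(
            0.0, config.weight_timing_jitter)
        thetaS_w = thetaP_w + wmean["thetaS_minus_thetaP"] + rng.normal(
            0.0, config.stop_timing_jitter)
        shape_w = dict(
            kE=wmean["kE"] * np.exp(rng.normal(0, config.rate_jitter)),
            TQ=wmean["TQ"] * np.exp(rng.normal(0, config.rate_jitter)),
            thetaP=thetaP_w,
            bP=wmean["bP"] * np.exp(rng.normal(0, config.width_jitter)),
            thetaS=thetaS_w,
            bS=wmean["bS"] * np.exp(rng.normal(0, config.width_jitter)),
        )
        wQ = wmean["wQ"] * (1 + config.weight_amp_loading * g
                            + rng.normal(0, config.weight_amp_jitter))
        wE = wmean["wE"] * (1 + config.weight_amp_loading * g
                            + rng.normal(0, config.weight_amp_jitter))
        wP = wmean["wP"] * (1 + config.weight_p_loading * g
                            + rng.normal(0, config.p_amp_jitter))
        whf = rng.normal(0.0, config.whf_sd)

        try:
            hparams = QEPSHeightParams(hQ, hE, hP, QEPSShape(**shape_h))
            wparams = QEPSWeightParams(wQ, wE, wP, QEPSShape(**shape_w), whf=whf)
        except ValueError:
            continue
        return hparams, wparams, float(whf)
    raise RuntimeError("could not draw an invariant-satisfying parameter set")


_H_FIELDS = ("hQ", "hE", "hP")
_W_FIELDS = ("wQ", "wE", "wP")
_SHAPE_FIELDS = ("kE", "TQ", "thetaP", "bP", "thetaS", "bS", "t0")


def _params_record(hparams: QEPSHeightParams, wparams: QEPSWeightParams) -> dict:
    rec = {f: getattr(hparams, f) for f in _H_FIELDS}
    rec.update({f"h_{f}": getattr(hparams.shape, f) for f in _SHAPE_FIELDS})
    rec.update({f: getattr(wparams, f) for f in _W_FIELDS})
    rec.update({f"w_{f}": getattr(wparams.shape, f) for f in _SHAPE_FIELDS})
    return rec


def generate_cohort(config: SyntheticCohortConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort measurements, hidden truth table).

    The measurement table is long-format: ``subject_id, sex, ga_weeks,
    age_years, height_cm, weight_kg`` with one row per visit, ages being
    postnatal decimal years.  True curves are functions of GA-corrected age;
    the truth table holds every true parameter plus derived landmarks and is
    kept separate for the recovery harness.
    """
    rng = np.random.default_rng(config.seed)
    rows, truth = [], []
    width = max(4, len(str(config.n)))
    schedule = np.asarray(config.schedule, float)
    for i in range(config.n):
        sex = "F" if i < config.n_female else "M"
        sid = f"S{i + 1:0{width}d}"
        ga = _truncnorm(rng, config.ga_mean, config.ga_sd, *config.ga_range)
        hparams, wparams, whf = sample_individual(config, sex, rng)
        # GA-corrected ages at the scheduled postnatal visit ages
        t = schedule - (40.0 - ga) * 7.0 / 365.25
        h_true = curve_value(hparams, t, "total")
        w_true = curve_value(wparams, t, "total") ** 2
        h_obs = h_true + rng.normal(0.0, config.height_noise_sd, t.size)
        w_obs = w_true * (1.0 + rng.normal(0.0, config.weight_noise_cv, t.size))
        for a, h, w in zip(schedule, h_obs, w_obs):
            rows.append((sid, sex, ga, a, h, w))
        lm = puberty_landmarks(hparams)
        rec = dict(subject_id=sid, sex=sex, ga_weeks=ga, whf=whf,
                   age_p5=lm.age_p5, age_p50=lm.age_p50, age_tphv=lm.age_tphv,
                   adult_height=curve_value(hparams, 25.0, "total"))
        rec.update(_params_record(hparams, wparams))
        truth.append(rec)
    cohort = pd.DataFrame(
        rows, columns=["subject_id", "sex", "ga_weeks", "age_years",
                       "height_cm", "weight_kg"])
    return cohort, pd.DataFrame(truth)


#: recovery pass thresholds: median |AgeP5 error| (y), median relative Pmax error
RECOVERY_THRESHOLDS = {"age_p5_median_abs_error": 0.15,
                       "pmax_median_rel_error": 0.05}


def recovery_report(truth: pd.DataFrame, fits: pd.DataFrame) -> dict:
    """Parameter/landmark recovery summary of fitted vs true values.

    ``fits`` is the flat per-subject record table produced by the fitting
    pipeline (one row per subject, same parameter column names as the truth
    table).  Returns bias / median absolute error / RMSE per quantity,
    overall and per sex, plus pass flags against the fixed thresholds.
    """
    t = truth.set_index("subject_id")
    f = fits.set_index("subject_id")
    common = t.index.intersection(f.index)
    if len(common) == 0 or len(common) < len(f.index):
        raise ValueError("truth and fit tables do not share matching subject ids")
    t, f = t.loc[common], f.loc[common]

    quantities = ["hQ", "hE", "hP", "h_thetaP", "h_bP", "h_thetaS", "h_bS",
                  "h_kE", "h_TQ", "age_p5", "age_tphv"]
    quantities = [q for q in quantities if q in f.columns and q in t.columns]

    def summary(tt, ff):
        out = {}
        for q in quantities:
            err = (ff[q] - tt[q]).to_numpy(float)
            err = err[np.isfinite(err)]
            out[q] = dict(bias=float(np.mean(err)),
                          median_abs_error=float(np.median(np.abs(err))),
                          rmse=float(np.sqrt(np.mean(err ** 2))))
        rel = ((ff["hP"] - tt["hP"]) / tt["hP"]).to_numpy(float)
        out["pmax_rel"] = dict(
            bias=float(np.mean(rel)),
            median_abs_error=float(np.median(np.abs(rel))),
            rmse=float(np.sqrt(np.mean(rel ** 2))))
        return out

    report = {"overall": summary(t, f), "by_sex": {}, "n": int(len(common))}
    for sex in sorted(t["sex"].unique()):
        m = t["sex"] == sex
        report["by_sex"][sex] = summary(t[m], f[m.to_numpy()])
    p5_err = report["overall"].get("age_p5", {}).get("median_abs_error", np.inf)
    pmax_err = report["overall"]["pmax_rel"]["median_abs_error"]
    report["thresholds"] = dict(RECOVERY_THRESHOLDS)
    report["passed"] = bool(
        p5_err <= RECOVERY_THRESHOLDS["age_p5_median_abs_error"]
        and pmax_err <= RECOVERY_THRESHOLDS["pmax_median_rel_error"])
    return report
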