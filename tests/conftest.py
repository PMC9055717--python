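import numpy as np
import pytest

from qepsgrowth.core import (
    QEPSHeightParams,
    QEPSShape,
    QEPSWeightParams,
    puberty_landmarks,
)
from qepsgrowth.fitting import FittedSubject, fit_cohort, subjects_from_frame
from qepsgrowth.synthetic import (
    SyntheticCohortConfig,
    generate_cohort,
    sample_individual,
)


@pytest.fixture
def default_shape():
    return QEPSShape(kE=1.48, TQ=19.0, thetaP=11.7, bP=0.7, thetaS=13.7, bS=1.2)


@pytest.fixture
def girl_params(default_shape):
    return QEPSHeightParams(hQ=89.57, hE=63.24, hP=20.95, shape=default_shape)


@pytest.fixture
def girl_weight_params():
    shape = QEPSShape(kE=1.47, TQ=19.5, thetaP=11.2, bP=0.5, thetaS=13.7, bS=1.0)
    return QEPSWeightParams(wQ=4.04, wE=2.40, wP=1.74, shape=shape)


def random_shape(rng: np.random.Generator) -> QEPSShape:
    """A random valid parameter shape spanning the plausible space."""
    theta_p = rng.uniform(8.5, 15.5)
    return QEPSShape(
        kE=rng.uniform(0.5, 2.5),
        TQ=rng.uniform(16.0, 23.0),
        thetaP=theta_p,
        bP=rng.uniform(0.35, 1.6),
        thetaS=theta_p + rng.uniform(0.8, 4.0),
        bS=rng.uniform(0.4, 2.2),
    )


def random_height_params(rng: np.random.Generator) -> QEPSHeightParams:
    return QEPSHeightParams(
        hQ=rng.uniform(60, 110), hE=rng.uniform(40, 90),
        hP=rng.uniform(5, 35), shape=random_shape(rng))


def true_fitted_subject(config, sex, rng, sid) -> FittedSubject:
    """A FittedSubject built from true sampled parameters (no fitting)."""
    hparams, wparams, whf = sample_individual(config, sex, rng)
    return FittedSubject(
        subject_id=sid, sex=sex, ga_weeks=40.0, height_params=hparams,
        weight_params=wparams, whf=whf, landmarks=puberty_landmarks(hparams))


@pytest.fixture(scope="session")
def population_config():
    return SyntheticCohortConfig(seed=505)


@pytest.fixture(scope="session")
def true_population(population_config):
    """800 subjects (400/sex) with known true curves, no fitting."""
    rng = np.random.default_rng(population_config.seed)
    subs = []
    for i in range(400):
        subs.append(true_fitted_subject(population_config, "F", rng, f"F{i:03d}"))
    for i in range(400):
        subs.append(true_fitted_subject(population_config, "M", rng, f"M{i:03d}"))
    return subs


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """A small noisy cohort generated and fitted once for fitting-level tests."""
    cfg = SyntheticCohortConfig(n=64, n_female=32, seed=99)
    cohort, truth = generate_cohort(cfg)
    subjects = subjects_from_frame(cohort)
    fitted = fit_cohort(subjects, seed=11, shrinkage=False)
    return dict(config=cfg, cohort=cohort, truth=truth, subjects=subjects,
                fitted=fitted)
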