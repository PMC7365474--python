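"""Heterogeneous individuals and the pre-study burn-in.

Each woman carries three individualized factors fixed for life: her age at
enrollment (uniform over the trial's age range), her tumor-aggressiveness
constant ``k`` (lognormal) and her maximum tumor diameter ``d_max``
(uniform).  Before the study starts, every candidate is simulated through a
burn-in window (default 6 years) during which cancers may arise, grow, and
be found by before-study self exams; women diagnosed or dead before study
start are ineligible and never enter a trial population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _engine
from ._engine import AgeBand, ScreeningSchedule
from ._rng import StreamFactory
from .params import ModelParams

__all__ = [
    "Individual",
    "EnrollmentState",
    "sample_individual",
    "run_burn_in",
    "generate_cohort",
    "export_cohort",
]


@dataclass(frozen=True)
class Individual:
    """One simulated woman: the individualized factors of the model."""

    id: int
    age_at_enroll: float
    k: float
    d_max: float
    seed: int

    def __post_init__(self) -> None:
        if self.k <= 0 or self.d_max <= 0:
            raise ValueError("k and d_max must be positive")


@dataclass(frozen=True)
class EnrollmentState:
    """Terminal state of the burn-in, at study start (t = 0).

    ``onset_time`` (years, negative) and ``diameter_at_enroll`` (mm) are
    present exactly when the woman enrolls with an undetected cancer.
    """

    status: str  # healthy | undetected_cancer | ineligible
    onset_time: float | None = None
    diameter_at_enroll: float | None = None
    ineligibility_cause: str | None = None  # diagnosed_pre_study | died_pre_study

    def __post_init__(self) -> None:
        if self.status not in ("healthy", "undetected_cancer", "ineligible"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "undetected_cancer" and (
            self.onset_time is None or self.diameter_at_enroll is None
        ):
            raise ValueError("undetected_cancer requires onset_time and diameter")
        if self.status == "ineligible" and self.ineligibility_cause not in (
            "diagnosed_pre_study", "died_pre_study"
        ):
            raise ValueError("ineligible requires a cause")


def sample_individual(
    rng: np.random.Generator,
    params: ModelParams,
    ident: int = 0,
    age_low: float = 40.0,
    age_high: float = 59.0,
) -> Individual:
    """Draw one woman: age ~ unif, log k ~ normal(mu_k, sigma_k), d_max ~ unif."""
    age = rng.uniform(age_low, age_high)
    k = float(np.exp(rng.normal(params.mu_k, params.sigma_k)))
    d_max = rng.uniform(params.d_max_low, params.d_max_high)
    seed = int(rng.integers(0, 2**31))
    return Individual(id=ident, age_at_enroll=float(age), k=k, d_max=d_max, seed=seed)


def run_burn_in(
    individual: Individual,
    params: ModelParams,
    rng: np.random.Generator,
) -> EnrollmentState:
    """Simulate the burn-in years ending at study start and classify.

    The woman starts healthy ``burn_in_years`` before t = 0.  Cancer onset
    follows the age-specific incidence rate; a tumor grows from a single
    cell and can only be found by the before-study self exam (half-detection
    diameter ``b_b2``); other-cause death runs throughout.
    """
    from . import natural_history as nh

    a = individual.age_at_enroll
    t0 = -params.burn_in_years
    t_onset = float(nh.inverse_cumulative_incidence(a, t0, rng.exponential(), params))
    t_other = float(nh.sample_other_cause_death(a, rng.uniform(), params, t_start=t0))

    times, codes = _engine.burn_in_exam_plan(params)
    u = rng.uniform(size=(1, times.size))
    det_time, det_diam, _ = _engine.first_detection(
        np.array([t_onset]), np.array([individual.k]), np.array([individual.d_max]),
        np.array([t_other]), times, codes, u, params, horizon=0.0,
    )
    det_time = float(det_time[0])

    if np.isfinite(det_time) and det_time < 0:
        return EnrollmentState(status="ineligible", ineligibility_cause="diagnosed_pre_study")
    if t_other < 0:
        return EnrollmentState(status="ineligible", ineligibility_cause="died_pre_study")
    if np.isfinite(t_onset) and t_onset < 0:
        d_now = float(_engine.diameter_at(
            np.array([0.0]), np.array([t_onset]),
            np.array([individual.k]), np.array([individual.d_max]), params)[0])
        return EnrollmentState(
            status="undetected_cancer", onset_time=t_onset, diameter_at_enroll=d_now
        )
    return EnrollmentState(status="healthy")


def generate_cohort(
    n_target: int,
    bands: Sequence[AgeBand],
    params: ModelParams,
    seed: int,
    horizon: float = 25.0,
    age_low: float = 40.0,
    age_high: float = 59.0,
) -> tuple[pd.DataFrame, int]:
    """Rejection-sample until exactly ``n_target`` eligible enrollees.

    Returns the eligible life table (the burn-in columns describe the
    enrollment state; in-study columns describe the subsequent course under
    ``bands``) and the number of rejected candidates.  Fully reproducible
    from ``seed``.
    """
    streams = StreamFactory(seed)
    return _engine.simulate_eligible_cohort(
        n_target, bands, params, streams, horizon,
        age_low=age_low, age_high=age_high,
    )


COHORT_COLUMNS = [
    "id", "age_at_enroll", "k", "d_max", "status_at_enroll",
    "onset_time", "diameter_at_enroll",
]


def export_cohort(cohort: pd.DataFrame, path) -> None:
    """Write one row per individual (enrollment view) as tab-separated text."""
    cohort[COHORT_COLUMNS].to_csv(path, sep="\t", index=False)
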