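"""Vectorized life-course engine shared by the public modules.

The engine works on numpy arrays, one entry per simulated woman, and is
exact in continuous time:

* Stage 1 (healthy): cancer onset and other-cause death are competing risks
  with closed-form cumulative hazards; both latent event times are drawn by
  analytic inverse-CDF, and the earlier one is the realized first event.
  This is distributionally identical to first-event sampling of the joint
  hazard and needs no time stepping.
* Stage 2 (undetected tumor): the tumor grows deterministically by the
  Gompertz law, and detection can only happen at discrete exam dates, where
  each exam is an independent Bernoulli trial at the current diameter.  The
  other-cause death clock keeps running.  On an exam day that coincides with
  the death day, the within-day rule (detection first, by default) decides.
* Stage 3 (detected): the cancer-death time is an exact Weibull inverse
  draw from the detection date; the earlier of cancer death and other-cause
  death wins.

Public modules (:mod:`bcham.population`, :mod:`bcham.simulator`,
:mod:`bcham.trial`) wrap this machinery with the domain-level API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import StreamFactory
from .params import DAYS_PER_YEAR, MONTHS_PER_YEAR, ModelParams

MODALITY_NAMES = ("before_study", "mammography", "physical", "self")
BEFORE_STUDY, MAMMOGRAPHY, PHYSICAL, SELF = range(4)

LIFE_COURSE_COLUMNS = [
    "id", "age_at_enroll", "k", "d_max", "onset_time", "eligible",
    "ineligibility_cause", "status_at_enroll", "diameter_at_enroll",
    "detect_time", "detect_diameter", "detect_modality",
    "death_time", "death_cause", "censor_time",
]


@dataclass(frozen=True)
class ScreeningSchedule:
    """Per-modality exam times (years from study start) for one age band.

    ``self_exams_per_year`` of ``None`` falls back to the model default.
    """

    mammography_times: tuple[float, ...] = ()
    physical_times: tuple[float, ...] = ()
    self_exams_per_year: float | None = None

    def __post_init__(self) -> None:
        for t in (*self.mammography_times, *self.physical_times):
            if t < 0:
                raise ValueError("exam times must be non-negative")
        if self.self_exams_per_year is not None and self.self_exams_per_year < 0:
            raise ValueError("self-exam cadence must be non-negative")


@dataclass(frozen=True)
class AgeBand:
    """Half-open age band [age_min, age_max) with its screening schedule."""

    age_min: float
    age_max: float
    schedule: ScreeningSchedule


def _cadence_times(per_year: float, start: float, stop: float) -> np.ndarray:
    """Mid-interval exam times at the given cadence over [start, stop)."""
    if per_year <= 0:
        return np.empty(0)
    n = int(np.floor((stop - start) * per_year + 1e-9))
    return start + (np.arange(n) + 0.5) / per_year


def burn_in_exam_plan(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Before-study self-exam times (negative years) and modality codes."""
    times = _cadence_times(params.before_study_exams_per_year, -params.burn_in_years, 0.0)
    return times, np.full(times.size, BEFORE_STUDY, dtype=np.int64)


def study_exam_plan(
    schedule: ScreeningSchedule, params: ModelParams, horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """In-study exam times/codes, sorted by time then modality priority.

    Mammography is evaluated before a physical exam falling on the same
    date, which is evaluated before a self exam.
    """
    cadence = (
        params.self_exams_per_year
        if schedule.self_exams_per_year is None
        else schedule.self_exams_per_year
    )
    self_times = _cadence_times(cadence, 0.0, horizon)
    times = np.concatenate([
        np.asarray(schedule.mammography_times, dtype=float),
        np.asarray(schedule.physical_times, dtype=float),
        self_times,
    ])
    codes = np.concatenate([
        np.full(len(schedule.mammography_times), MAMMOGRAPHY, dtype=np.int64),
        np.full(len(schedule.physical_times), PHYSICAL, dtype=np.int64),
        np.full(self_times.size, SELF, dtype=np.int64),
    ])
    order = np.lexsort((codes, times))
    return times[order], codes[order]


def band_indices(ages: np.ndarray, bands: Sequence[AgeBand]) -> np.ndarray:
    """Assign each age to its band index; every age must be covered."""
    idx = np.full(ages.shape, -1, dtype=np.int64)
    for j, band in enumerate(bands):
        in_band = (ages >= band.age_min) & (ages < band.age_max)
        idx[in_band] = j
    if np.any(idx < 0):
        bad = float(ages[idx < 0][0])
        raise ValueError(f"age {bad:.2f} not covered by any age band")
    return idx


_BLOCK_COLS = 384


def first_detection(
    t_onset: np.ndarray,
    k: np.ndarray,
    d_max: np.ndarray,
    t_other: np.ndarray,
    exam_times: np.ndarray,
    exam_codes: np.ndarray,
    u: np.ndarray | None,
    params: ModelParams,
    horizon: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First successful exam for each woman, or +inf if never detected.

    Exam uniforms come either from ``u`` (shape (n, len(exam_times));
    column j is the j-th exam of the plan) or are drawn from ``rng`` as
    needed.  The plan is processed in column blocks with rows retired as
    soon as they are detected, dead, or censored, which keeps both memory
    and work bounded when the plan is dense (e.g. daily self exams).
    Returns (time, diameter, modality code) with +inf / nan / -1 where
    there is no detection.
    """
    n = t_onset.shape[0]
    m = exam_times.size
    if m == 0 or n == 0:
        return (np.full(n, np.inf), np.full(n, np.nan), np.full(n, -1, dtype=np.int64))
    if (u is None) == (rng is None):
        raise ValueError("pass exactly one of u or rng")

    det_time = np.full(n, np.inf)
    det_diam = np.full(n, np.nan)
    det_code = np.full(n, -1, dtype=np.int64)

    b2_all = np.array([params.b_b2, params.b_m2, params.b_p2, params.b_s2])
    b2_col = b2_all[exam_codes]
    log_ratio = np.log(params.d0 / d_max)  # < 0, column-invariant per woman
    f = params.growth_exponent_factor
    # last instant an exam can still count: death day (inclusive under the
    # detection-first rule) or the follow-up horizon
    day = 1.0 / DAYS_PER_YEAR
    if params.detection_before_death_same_day:
        t_last = np.minimum((np.floor(t_other / day) + 1.0) * day, horizon)
    else:
        t_last = np.minimum(t_other, horizon)

    undetected = np.ones(n, dtype=bool)
    for lo in range(0, m, _BLOCK_COLS):
        hi = min(lo + _BLOCK_COLS, m)
        te = exam_times[lo:hi]
        if te[0] >= horizon:
            break
        rows = np.where(undetected & (t_onset < te[-1]) & (t_last > te[0]))[0]
        if rows.size == 0:
            continue
        rel_months = (te[None, :] - t_onset[rows, None]) * MONTHS_PER_YEAR
        growing = rel_months > 0
        expo = np.exp(-f * k[rows, None] * np.where(growing, rel_months, 0.0))
        diam = d_max[rows, None] * np.exp(log_ratio[rows, None] * expo)
        x = (diam - b2_col[None, lo:hi]) / params.b1
        prob = 1.0 / (1.0 + np.exp(-x))

        if params.detection_before_death_same_day:
            alive = te[None, :] < t_last[rows, None]
        else:
            alive = te[None, :] < t_other[rows, None]
        uc = u[rows, lo:hi] if u is not None else rng.uniform(size=(rows.size, hi - lo))
        hit = growing & alive & (te[None, :] < horizon) & (uc < prob)
        any_hit = hit.any(axis=1)
        if any_hit.any():
            first = np.argmax(hit[any_hit], axis=1)
            got = rows[any_hit]
            det_time[got] = te[first]
            det_diam[got] = diam[any_hit, first]
            det_code[got] = exam_codes[lo:hi][first]
            undetected[got] = False
    return det_time, det_diam, det_code


def diameter_at(t: np.ndarray, t_onset: np.ndarray, k: np.ndarray,
                d_max: np.ndarray, params: ModelParams) -> np.ndarray:
    """Gompertz diameter at time ``t`` (years) for onset at ``t_onset``."""
    rel = np.maximum((t - t_onset) * MONTHS_PER_YEAR, 0.0)
    expo = np.exp(-params.growth_exponent_factor * k * rel)
    return d_max * (params.d0 / d_max) ** expo


def resolve_life_courses(
    ids: np.ndarray,
    age: np.ndarray,
    k: np.ndarray,
    d_max: np.ndarray,
    t_onset: np.ndarray,
    t_other: np.ndarray,
    det_time: np.ndarray,
    det_diam: np.ndarray,
    det_code: np.ndarray,
    u_cancer: np.ndarray,
    params: ModelParams,
    horizon: float,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Classify enrollment state, settle Stage 3, and emit the life table."""
    n = age.shape[0]
    has_det = np.isfinite(det_time)

    died_pre = t_other < 0
    diag_pre = has_det & (det_time < 0)
    ineligible = died_pre | diag_pre
    # detection cannot follow death, so if diag_pre the diagnosis came first
    cause = np.where(diag_pre, "diagnosed_pre_study",
                     np.where(died_pre, "died_pre_study", ""))

    has_onset = np.isfinite(t_onset)
    undet_at_enroll = ~ineligible & has_onset & (t_onset < 0)
    status = np.where(ineligible, "ineligible",
                      np.where(undet_at_enroll, "undetected_cancer", "healthy"))
    d_enroll = np.full(n, np.nan)
    if undet_at_enroll.any():
        rows = undet_at_enroll
        d_enroll[rows] = diameter_at(np.zeros(rows.sum()), t_onset[rows],
                                     k[rows], d_max[rows], params)

    # Stage 3: exact Weibull inverse from detection; the post-detection
    # hazard clock runs in years (see methods note on the time unit)
    a_eff = params.alpha_eff if alpha is None else float(alpha)
    t_cancer = np.full(n, np.inf)
    if has_det.any():
        rows = has_det
        rate = k[rows] ** a_eff * det_diam[rows] ** params.Z
        tau_years = (-np.log(u_cancer[rows]) / rate) ** (1.0 / params.omega)
        t_cancer[rows] = det_time[rows] + tau_years

    t_death = np.minimum(t_other, t_cancer)
    died = t_death < horizon
    death_time = np.where(died, t_death, np.nan)
    death_cause = np.where(died, np.where(t_cancer < t_other, "cancer", "other"), "")

    modality = np.where(det_code >= 0,
                        np.array(MODALITY_NAMES + ("",))[det_code], "")
    return pd.DataFrame({
        "id": ids,
        "age_at_enroll": age,
        "k": k,
        "d_max": d_max,
        "onset_time": np.where(has_onset, t_onset, np.nan),
        "eligible": ~ineligible,
        "ineligibility_cause": cause,
        "status_at_enroll": status,
        "diameter_at_enroll": d_enroll,
        "detect_time": np.where(has_det, det_time, np.nan),
        "detect_diameter": det_diam,
        "detect_modality": modality,
        "death_time": death_time,
        "death_cause": death_cause,
        "censor_time": np.full(n, float(horizon)),
    })


def draw_attributes(
    streams: StreamFactory,
    key: tuple[int, ...],
    n: int,
    params: ModelParams,
    age_low: float,
    age_high: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (age, k, d_max) for ``n`` women from dedicated streams."""
    age = streams.rng("age", *key).uniform(age_low, age_high, n)
    k = np.exp(streams.rng("k", *key).normal(params.mu_k, params.sigma_k, n))
    d_max = streams.rng("d_max", *key).uniform(params.d_max_low, params.d_max_high, n)
    return age, k, d_max


def draw_stage1(
    streams: StreamFactory,
    key: tuple[int, ...],
    age: np.ndarray,
    params: ModelParams,
    t_start: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent onset and other-cause death times from ``t_start`` (years)."""
    from . import natural_history as nh

    n = age.shape[0]
    e_onset = streams.rng("onset", *key).exponential(size=n)
    t_onset = nh.inverse_cumulative_incidence(age, t_start, e_onset, params)
    u_other = streams.rng("other_death", *key).uniform(size=n)
    t_other = nh.sample_other_cause_death(age, u_other, params, t_start=t_start)
    return np.atleast_1d(t_onset), np.atleast_1d(t_other)


def simulate_batch(
    streams: StreamFactory,
    key: tuple[int, ...],
    id_offset: int,
    n: int,
    bands: Sequence[AgeBand],
    params: ModelParams,
    horizon: float,
    age_low: float,
    age_high: float,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` fresh candidates end to end (burn-in through horizon)."""
    age, k, d_max = draw_attributes(streams, key, n, params, age_low, age_high)
    t_onset, t_other = draw_stage1(streams, key, age, params, -params.burn_in_years)

    # detection can only concern women whose cancer actually starts
    onset_rows = np.where(np.isfinite(t_onset))[0]

    bi_times, bi_codes = burn_in_exam_plan(params)
    det_b_time = np.full(n, np.inf)
    det_b_diam = np.full(n, np.nan)
    det_b_code = np.full(n, -1, dtype=np.int64)
    t, d, c = first_detection(
        t_onset[onset_rows], k[onset_rows], d_max[onset_rows],
        t_other[onset_rows], bi_times, bi_codes, None, params, horizon,
        rng=streams.rng("detect_burn_in", *key))
    det_b_time[onset_rows], det_b_diam[onset_rows], det_b_code[onset_rows] = t, d, c

    plans = [study_exam_plan(b.schedule, params, horizon) for b in bands]
    rng_study = streams.rng("detect_study", *key)
    det_s_time = np.full(n, np.inf)
    det_s_diam = np.full(n, np.nan)
    det_s_code = np.full(n, -1, dtype=np.int64)
    bidx = band_indices(age, bands)
    for j, (times, codes) in enumerate(plans):
        rows = onset_rows[bidx[onset_rows] == j]
        if rows.size == 0 or times.size == 0:
            continue
        t, d, c = first_detection(t_onset[rows], k[rows], d_max[rows],
                                  t_other[rows], times, codes,
                                  None, params, horizon, rng=rng_study)
        det_s_time[rows], det_s_diam[rows], det_s_code[rows] = t, d, c

    # burn-in exams all precede in-study exams, so a burn-in hit wins
    use_b = np.isfinite(det_b_time)
    det_time = np.where(use_b, det_b_time, det_s_time)
    det_diam = np.where(use_b, det_b_diam, det_s_diam)
    det_code = np.where(use_b, det_b_code, det_s_code)

    u_cancer = streams.rng("cancer_death", *key).uniform(size=n)
    ids = id_offset + np.arange(n, dtype=np.int64)
    return resolve_life_courses(ids, age, k, d_max, t_onset, t_other,
                                det_time, det_diam, det_code, u_cancer,
                                params, horizon, alpha=alpha)


def simulate_eligible_cohort(
    n_target: int,
    bands: Sequence[AgeBand],
    params: ModelParams,
    streams: StreamFactory,
    horizon: float,
    key: tuple[int, ...] = (),
    age_low: float = 40.0,
    age_high: float = 59.0,
    batch_size: int = 25_000,
    alpha: float | None = None,
) -> tuple[pd.DataFrame, int]:
    """Accumulate batches until ``n_target`` eligible women are enrolled.

    Returns the eligible life table (exactly ``n_target`` rows, re-indexed
    0..n_target-1) and the number of rejected candidates.  Batches are keyed
    by their index, so the draws of earlier candidates never depend on how
    many more are needed.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    kept: list[pd.DataFrame] = []
    n_kept = 0
    n_rejected = 0
    batch = 0
    while n_kept < n_target:
        n_draw = min(batch_size, max(2048, int(1.05 * (n_target - n_kept)) + 64))
        df = simulate_batch(streams, (*key, batch), batch * batch_size, n_draw,
                            bands, params, horizon, age_low, age_high, alpha=alpha)
        elig = df[df["eligible"]]
        n_rejected += len(df) - len(elig)
        kept.append(elig)
        n_kept += len(elig)
        batch += 1
    cohort = pd.concat(kept, ignore_index=True).iloc[:n_target].reset_index(drop=True)
    return cohort, n_rejected
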