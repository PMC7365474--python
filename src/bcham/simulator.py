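"""Per-individual life-course engine over the five disease stages.

A woman moves healthy -> undetected cancer -> detected cancer, with
other-cause death possible from every living stage and cancer death only
after detection.  Stage 1 and the death clocks are sampled exactly by
inverse CDF; detection happens only at scheduled exam dates (mammography,
physical exam, self exam), each an independent Bernoulli trial at the
current Gompertz diameter.

The module exposes both a scalar API (one :class:`LifeCourse` per call,
used for inspection and testing) and vectorized cohort entry points
(:func:`sample_cancer_patients`, :func:`simulate_paired_cohort`) used by
the trial and outcomes layers.  Both run through the same engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _engine
from . import natural_history as nh
from ._engine import (  # noqa: F401  (public re-exports)
    AgeBand,
    MODALITY_NAMES,
    ScreeningSchedule,
)
from ._rng import StreamFactory
from .params import MONTHS_PER_YEAR, ModelParams
from .population import EnrollmentState, Individual

__all__ = [
    "ScreeningSchedule", "AgeBand", "LifeCourse",
    "sample_onset", "simulate_undetected_phase", "simulate_detected_phase",
    "simulate_individual", "run_paired_replicates",
    "sample_cancer_patients", "simulate_paired_cohort", "export_event_log",
]


@dataclass(frozen=True)
class LifeCourse:
    """Event history of one woman, times in years from study start."""

    individual_id: int
    onset_time: float | None = None
    detection: tuple[float, float, str] | None = None  # (time, d_de, modality)
    death: tuple[float, str] | None = None  # (time, cause in {cancer, other})
    censor_time: float = 25.0

    def __post_init__(self) -> None:
        if self.detection is not None:
            if self.onset_time is None or self.detection[0] < self.onset_time:
                raise ValueError("detection requires an earlier onset")
        if self.death is not None and self.death[1] == "cancer":
            if self.detection is None or self.death[0] < self.detection[0]:
                raise ValueError("cancer death requires an earlier detection")

    @property
    def alive_at_censor(self) -> bool:
        return self.death is None

    def stage_at(self, t: float) -> str:
        """Compartment occupied just before ``t`` (events at exactly ``t``
        have not yet taken effect; the five stages partition)."""
        if self.death is not None and self.death[0] < t:
            return "cancer_death" if self.death[1] == "cancer" else "other_death"
        if self.detection is not None and self.detection[0] < t:
            return "detected"
        if self.onset_time is not None and self.onset_time < t:
            return "undetected"
        return "healthy"


def sample_onset(
    age_at_enroll: float,
    horizon: float,
    params: ModelParams,
    rng: np.random.Generator,
    t_start: float = 0.0,
) -> tuple[str | None, float | None]:
    """First event of the healthy stage within the horizon, sampled exactly.

    Cancer onset (rate c_a) and other-cause death (rate h_a) compete; both
    latent times are drawn by analytic inversion of their cumulative
    hazards and the earlier one within ``horizon`` is returned as
    ``("onset", t)`` or ``("death", t)``; ``(None, None)`` means the woman
    reached the horizon healthy.
    """
    if horizon <= t_start:
        raise ValueError("horizon must exceed t_start")
    t_on = float(nh.inverse_cumulative_incidence(
        age_at_enroll, t_start, rng.exponential(), params))
    t_de = float(nh.sample_other_cause_death(
        age_at_enroll, rng.uniform(), params, t_start=t_start))
    t_first = min(t_on, t_de)
    if t_first >= horizon:
        return None, None
    return ("onset", t_on) if t_on < t_de else ("death", t_de)


def _study_plan(schedule: ScreeningSchedule, params: ModelParams, horizon: float):
    return _engine.study_exam_plan(schedule, params, horizon)


def simulate_undetected_phase(
    onset_time: float,
    individual: Individual,
    schedule: ScreeningSchedule,
    params: ModelParams,
    rng: np.random.Generator,
    horizon: float = 25.0,
    t_other: float | None = None,
) -> tuple[str, float | None, float | None, str | None]:
    """Follow an undetected tumor from onset until detection, death or censor.

    Returns ``("detected", time, diameter, modality)``,
    ``("died_other", time, None, None)`` or ``("censored", horizon, None,
    None)``.  ``t_other`` may carry a latent other-cause death time already
    drawn upstream; otherwise one is drawn conditional on being alive at
    onset.
    """
    if t_other is None:
        t_other = float(nh.sample_other_cause_death(
            individual.age_at_enroll, rng.uniform(), params,
            t_start=max(onset_time, -params.burn_in_years)))
    times, codes = _study_plan(schedule, params, horizon)
    u = rng.uniform(size=(1, times.size))
    det_time, det_diam, det_code = _engine.first_detection(
        np.array([onset_time]), np.array([individual.k]),
        np.array([individual.d_max]), np.array([t_other]),
        times, codes, u, params, horizon)
    if np.isfinite(det_time[0]):
        return ("detected", float(det_time[0]), float(det_diam[0]),
                MODALITY_NAMES[int(det_code[0])])
    if t_other < horizon:
        return ("died_other", float(t_other), None, None)
    return ("censored", float(horizon), None, None)


def simulate_detected_phase(
    detection: tuple[float, float, str],
    individual: Individual,
    params: ModelParams,
    rng: np.random.Generator,
    horizon: float = 25.0,
    t_other: float | None = None,
    alpha: float | None = None,
) -> tuple[str, float]:
    """Resolve the detected stage: cancer death, other death, or censoring.

    The cancer-death time is an exact Weibull inverse draw from detection;
    the earlier of the two death clocks wins.
    """
    t_d, d_de, _ = detection
    if d_de <= 0:
        raise ValueError("detected diameter must be positive")
    if t_other is None:
        t_other = float(nh.sample_other_cause_death(
            individual.age_at_enroll, rng.uniform(), params, t_start=t_d))
    tau_years = float(nh.sample_cancer_death_time(
        d_de, individual.k, rng.uniform(), params, alpha=alpha))
    t_cancer = t_d + tau_years
    t_death = min(t_cancer, t_other)
    if t_death >= horizon:
        return ("censored", float(horizon))
    return ("cancer", float(t_cancer)) if t_cancer < t_other else ("other", float(t_other))


def simulate_individual(
    individual: Individual,
    enrollment_state: EnrollmentState,
    schedule: ScreeningSchedule,
    params: ModelParams,
    rng: np.random.Generator,
    horizon: float = 25.0,
    alpha: float | None = None,
) -> LifeCourse:
    """Compose the three phases into one complete life course."""
    if enrollment_state.status == "ineligible":
        raise ValueError("ineligible individuals cannot be simulated in-study")

    # one latent other-cause death clock for the whole course, conditional
    # on being alive at study start
    t_other = float(nh.sample_other_cause_death(
        individual.age_at_enroll, rng.uniform(), params, t_start=0.0))

    if enrollment_state.status == "undetected_cancer":
        onset: float | None = float(enrollment_state.onset_time)  # type: ignore[arg-type]
    else:
        t_on = float(nh.inverse_cumulative_incidence(
            individual.age_at_enroll, 0.0, rng.exponential(), params))
        onset = t_on if np.isfinite(t_on) and t_on < min(t_other, horizon) else None

    if onset is None:
        death = (t_other, "other") if t_other < horizon else None
        return LifeCourse(individual.id, None, None, death, horizon)

    kind, t1, d_de, modality = simulate_undetected_phase(
        onset, individual, schedule, params, rng, horizon, t_other=t_other)
    if kind == "died_other":
        return LifeCourse(individual.id, onset, None, (t1, "other"), horizon)
    if kind == "censored":
        return LifeCourse(individual.id, onset, None, None, horizon)

    detection = (t1, d_de, modality)
    outcome, t2 = simulate_detected_phase(
        detection, individual, params, rng, horizon, t_other=t_other, alpha=alpha)
    death = None if outcome == "censored" else (t2, outcome)
    return LifeCourse(individual.id, onset, detection, death, horizon)


def run_paired_replicates(
    individual: Individual,
    enrollment_state: EnrollmentState,
    arm_schedules: Mapping[str, ScreeningSchedule],
    n_per_arm: int,
    params: ModelParams,
    seed: int,
    horizon: float = 25.0,
    alpha: float | None = None,
) -> dict[str, list[LifeCourse]]:
    """Simulate one woman ``n_per_arm`` times per arm with shared onset.

    For each replicate pair the onset time and the other-cause death clock
    are drawn once and shared across arms (common random numbers);
    detection trials and the cancer-death draw are arm-specific.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    streams = StreamFactory(seed)
    arm_names = list(arm_schedules)
    out: dict[str, list[LifeCourse]] = {name: [] for name in arm_names}
    a = individual.age_at_enroll
    for r in range(n_per_arm):
        shared = streams.rng("onset", r)
        t_other = float(nh.sample_other_cause_death(
            a, shared.uniform(), params, t_start=0.0))
        if enrollment_state.status == "undetected_cancer":
            onset: float | None = float(enrollment_state.onset_time)  # type: ignore[arg-type]
        else:
            t_on = float(nh.inverse_cumulative_incidence(a, 0.0, shared.exponential(), params))
            onset = t_on if np.isfinite(t_on) and t_on < min(t_other, horizon) else None
        for j, name in enumerate(arm_names):
            arm_rng = streams.rng("detect_study", r, j)
            if onset is None:
                death = (t_other, "other") if t_other < horizon else None
                out[name].append(LifeCourse(individual.id, None, None, death, horizon))
                continue
            kind, t1, d_de, modality = simulate_undetected_phase(
                onset, individual, arm_schedules[name], params, arm_rng,
                horizon, t_other=t_other)
            if kind == "died_other":
                out[name].append(LifeCourse(individual.id, onset, None, (t1, "other"), horizon))
            elif kind == "censored":
                out[name].append(LifeCourse(individual.id, onset, None, None, horizon))
            else:
                detection = (t1, d_de, modality)
                outcome, t2 = simulate_detected_phase(
                    detection, individual, params,
                    streams.rng("cancer_death", r, j), horizon,
                    t_other=t_other, alpha=alpha)
                death = None if outcome == "censored" else (t2, outcome)
                out[name].append(LifeCourse(individual.id, onset, detection, death, horizon))
    return out


# ---------------------------------------------------------------------------
# vectorized cohort-level paired analysis


def sample_cancer_patients(
    n: int,
    params: ModelParams,
    seed: int,
    horizon: float = 25.0,
    age_low: float = 40.0,
    age_high: float = 59.0,
    batch_size: int = 25_000,
) -> pd.DataFrame:
    """Sample ``n`` women conditioned on acquiring cancer.

    The onset time is drawn from the burn-in-to-horizon incidence process
    and kept only if it falls before the horizon; accepted women carry that
    onset for every subsequent paired replicate ("identical parameters and
    time of onset").  Death competition is handled per replicate, not here.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    streams = StreamFactory(seed)
    kept: list[pd.DataFrame] = []
    n_kept = 0
    batch = 0
    while n_kept < n:
        m = batch_size
        age, k, d_max = _engine.draw_attributes(
            streams, (batch,), m, params, age_low, age_high)
        e = streams.rng("onset", batch).exponential(size=m)
        t_onset = np.atleast_1d(nh.inverse_cumulative_incidence(
            age, -params.burn_in_years, e, params))
        accept = np.isfinite(t_onset) & (t_onset < horizon)
        df = pd.DataFrame({
            "id": batch * batch_size + np.arange(m, dtype=np.int64),
            "age_at_enroll": age, "k": k, "d_max": d_max,
            "onset_time": t_onset,
        })[accept]
        kept.append(df)
        n_kept += int(accept.sum())
        batch += 1
    return pd.concat(kept, ignore_index=True).iloc[:n].reset_index(drop=True)


def simulate_paired_cohort(
    patients: pd.DataFrame,
    arm_bands: Mapping[str, Sequence[AgeBand]],
    n_pairs: int,
    params: ModelParams,
    seed: int,
    horizon: float = 25.0,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Paired-arm simulation of fixed-onset patients, vectorized.

    Each of the ``n_pairs`` replicate pairs shares the other-cause death
    clock and the burn-in detection draws across arms; in-study detection
    and cancer-death draws are arm-specific.  Returns one life-table row
    per (patient, pair, arm); replicates where the patient was diagnosed
    or died before study start are marked ineligible (shared across arms).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    streams = StreamFactory(seed)
    n = len(patients)
    age = patients["age_at_enroll"].to_numpy(float)
    k = patients["k"].to_numpy(float)
    d_max = patients["d_max"].to_numpy(float)
    t_onset = patients["onset_time"].to_numpy(float)
    ids = patients["id"].to_numpy(np.int64)

    bi_times, bi_codes = _engine.burn_in_exam_plan(params)
    arm_names = list(arm_bands)
    frames: list[pd.DataFrame] = []
    for r in range(n_pairs):
        u_other = streams.rng("other_death", r).uniform(size=n)
        t_other = np.atleast_1d(nh.sample_other_cause_death(
            age, u_other, params, t_start=-params.burn_in_years))
        det_b = _engine.first_detection(
            t_onset, k, d_max, t_other, bi_times, bi_codes, None, params,
            horizon, rng=streams.rng("detect_burn_in", r))

        for j, name in enumerate(arm_names):
            bands = arm_bands[name]
            plans = [_engine.study_exam_plan(b.schedule, params, horizon) for b in bands]
            rng_study = streams.rng("detect_study", r, j)
            det_time = np.full(n, np.inf)
            det_diam = np.full(n, np.nan)
            det_code = np.full(n, -1, dtype=np.int64)
            bidx = _engine.band_indices(age, bands)
            for b, (times, codes) in enumerate(plans):
                rows = np.where(bidx == b)[0]
                if rows.size == 0 or times.size == 0:
                    continue
                t, d, c = _engine.first_detection(
                    t_onset[rows], k[rows], d_max[rows], t_other[rows],
                    times, codes, None, params, horizon, rng=rng_study)
                det_time[rows], det_diam[rows], det_code[rows] = t, d, c
            use_b = np.isfinite(det_b[0])
            det_time = np.where(use_b, det_b[0], det_time)
            det_diam = np.where(use_b, det_b[1], det_diam)
            det_code = np.where(use_b, det_b[2], det_code)

            u_cancer = streams.rng("cancer_death", r, j).uniform(size=n)
            df = _engine.resolve_life_courses(
                ids, age, k, d_max, t_onset, t_other,
                det_time, det_diam, det_code, u_cancer, params, horizon,
                alpha=alpha)
            df.insert(1, "pair", r)
            df.insert(2, "arm", name)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def export_event_log(life_table: pd.DataFrame, path) -> None:
    """Stream a life table to a long event log (one row per event)."""
    rows = []
    has_pair = "pair" in life_table.columns
    for _, row in life_table.iterrows():
        base = {
            "id": row["id"],
            "replicate": row["pair"] if has_pair else 0,
            "arm": row.get("arm", ""),
        }
        if np.isfinite(row.get("onset_time", np.nan)):
            rows.append({**base, "event": "onset", "time": row["onset_time"],
                         "diameter": "", "modality": "", "cause": ""})
        if np.isfinite(row.get("detect_time", np.nan)):
            rows.append({**base, "event": "detection", "time": row["detect_time"],
                         "diameter": row["detect_diameter"],
                         "modality": row["detect_modality"], "cause": ""})
        if np.isfinite(row.get("death_time", np.nan)):
            rows.append({**base, "event": "death", "time": row["death_time"],
                         "diameter": "", "modality": "",
                         "cause": row["death_cause"]})
        rows.append({**base, "event": "censor", "time": row["censor_time"],
                     "diameter": "", "modality": "", "cause": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
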