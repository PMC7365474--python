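"""Two-arm screening-trial design and trial-level aggregation.

Encodes the CNBSS layout: 89,835 women aged 40-59 randomized to a
mammography arm (annual mammography + physical exam at years 0-4) or a
control arm (ages 40-49: a single physical exam at enrollment; ages 50-59:
annual physical exams at years 0-4), followed for up to 25 years.  Both
arms additionally carry the regular self-exam channel throughout follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _engine
from ._engine import AgeBand, ScreeningSchedule
from ._rng import StreamFactory
from .params import ModelParams

__all__ = [
    "ArmDesign", "TrialDesign", "TrialResult",
    "cnbss_design", "run_trial", "census", "summarize_ages",
]

CNBSS_TOTAL = 89_835
SCREENING_PHASE_YEARS = 5.0


@dataclass(frozen=True)
class ArmDesign:
    name: str
    size: int
    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("arm size must be >= 1")


@dataclass(frozen=True)
class TrialDesign:
    arms: tuple[ArmDesign, ...]
    horizon: float = 25.0
    age_low: float = 40.0
    age_high: float = 59.0

    def arm(self, name: str) -> ArmDesign:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def total_size(self) -> int:
        return sum(a.size for a in self.arms)


def cnbss_design(
    mammography_size: int = 44_918,
    control_size: int = 44_917,
    horizon: float = 25.0,
) -> TrialDesign:
    """The CNBSS two-arm design with its per-age-band exam schedules."""
    screen_years = (0.0, 1.0, 2.0, 3.0, 4.0)
    mam = ArmDesign(
        name="mammography",
        size=mammography_size,
        bands=(AgeBand(40.0, 60.0, ScreeningSchedule(
            mammography_times=screen_years, physical_times=screen_years)),),
    )
    ctrl = ArmDesign(
        name="control",
        size=control_size,
        bands=(
            AgeBand(40.0, 50.0, ScreeningSchedule(physical_times=(0.0,))),
            AgeBand(50.0, 60.0, ScreeningSchedule(physical_times=screen_years)),
        ),
    )
    return TrialDesign(arms=(mam, ctrl), horizon=horizon)


@dataclass
class TrialResult:
    """Aggregated outcome of one trial simulation."""

    design: TrialDesign
    params: ModelParams
    seed: int
    arm_tables: dict[str, pd.DataFrame]  # eligible life table per arm
    rejected: dict[str, int] = field(default_factory=dict)

    def annual_series(self) -> pd.DataFrame:
        """Per-arm annual counts (study year y covers t in [y-1, y))."""
        rows = []
        horizon = self.design.horizon
        for name, tab in self.arm_tables.items():
            years = np.arange(1, int(np.ceil(horizon)) + 1)
            dx = tab["detect_time"].to_numpy(float)
            death_t = tab["death_time"].to_numpy(float)
            cause = tab["death_cause"].to_numpy()
            for y in years:
                lo, hi = float(y - 1), float(y)
                rows.append({
                    "arm": name, "study_year": int(y),
                    "diagnoses": int(np.sum((dx >= lo) & (dx < hi))),
                    "cancer_deaths": int(np.sum(
                        (death_t >= lo) & (death_t < hi) & (cause == "cancer"))),
                    "other_deaths": int(np.sum(
                        (death_t >= lo) & (death_t < hi) & (cause == "other"))),
                })
        return pd.DataFrame(rows)

    def diagnoses(self, arm: str) -> pd.DataFrame:
        tab = self.arm_tables[arm]
        dx = tab[np.isfinite(tab["detect_time"].to_numpy(float))].copy()
        dx["age_at_diagnosis"] = dx["age_at_enroll"] + dx["detect_time"]
        dx["study_year"] = np.floor(dx["detect_time"]).astype(int) + 1
        return dx

    def cancer_deaths(self, arm: str) -> pd.DataFrame:
        tab = self.arm_tables[arm]
        dd = tab[tab["death_cause"] == "cancer"].copy()
        dd["age_at_death"] = dd["age_at_enroll"] + dd["death_time"]
        return dd


def run_trial(design: TrialDesign, params: ModelParams, seed: int) -> TrialResult:
    """Simulate every arm of the trial (independent cohorts per arm).

    Randomization is emulated by drawing each arm's cohort from identical
    distributions; individuals are not shared across arms.  Reproducible
    from ``seed``.
    """
    streams = StreamFactory(seed)
    arm_tables: dict[str, pd.DataFrame] = {}
    rejected: dict[str, int] = {}
    for i, arm in enumerate(design.arms):
        tab, n_rej = _engine.simulate_eligible_cohort(
            arm.size, arm.bands, params, streams, design.horizon,
            key=(i,), age_low=design.age_low, age_high=design.age_high)
        arm_tables[arm.name] = tab
        rejected[arm.name] = n_rej
    return TrialResult(design=design, params=params, seed=seed,
                       arm_tables=arm_tables, rejected=rejected)


_STAGES = ("healthy", "undetected", "detected", "cancer_death", "other_death")


def census(result: TrialResult, t: float, arm: str | None = None) -> dict[str, int]:
    """Counts of the five compartments at time ``t`` (sums to arm size)."""
    if not 0.0 <= t <= result.design.horizon:
        raise ValueError("t must lie within [0, horizon]")
    tabs = ([result.arm_tables[arm]] if arm is not None
            else list(result.arm_tables.values()))
    counts = dict.fromkeys(_STAGES, 0)
    for tab in tabs:
        onset = tab["onset_time"].to_numpy(float)
        det = tab["detect_time"].to_numpy(float)
        death = tab["death_time"].to_numpy(float)
        cause = tab["death_cause"].to_numpy()
        dead = np.isfinite(death) & (death < t)
        counts["cancer_death"] += int(np.sum(dead & (cause == "cancer")))
        counts["other_death"] += int(np.sum(dead & (cause == "other")))
        alive = ~dead
        detected = alive & np.isfinite(det) & (det < t)
        counts["detected"] += int(np.sum(detected))
        undet = alive & ~detected & np.isfinite(onset) & (onset < t)
        counts["undetected"] += int(np.sum(undet))
        counts["healthy"] += int(np.sum(alive & ~detected & ~undet))
    return counts


def summarize_ages(result: TrialResult,
                   screening_phase: float = SCREENING_PHASE_YEARS) -> pd.DataFrame:
    """Mean and range of ages at diagnosis / at cancer death, by arm.

    Restricted to cancers detected during the screening phase (detection
    before the end of study year ``screening_phase``); cancer deaths are
    those occurring within the follow-up horizon among those cancers.
    """
    rows = []
    for name in result.arm_tables:
        dx = result.diagnoses(name)
        phase = dx[dx["detect_time"] < screening_phase]
        ages_dx = phase["age_at_diagnosis"].to_numpy(float)
        died = phase[phase["death_cause"] == "cancer"]
        ages_dd = (died["age_at_enroll"] + died["death_time"]).to_numpy(float)
        rows.append({
            "arm": name,
            "n_diagnosed_screening_phase": int(len(phase)),
            "mean_age_at_diagnosis": round(float(np.mean(ages_dx)), 2) if len(ages_dx) else np.nan,
            "min_age_at_diagnosis": round(float(np.min(ages_dx)), 2) if len(ages_dx) else np.nan,
            "max_age_at_diagnosis": round(float(np.max(ages_dx)), 2) if len(ages_dx) else np.nan,
            "n_cancer_deaths": int(len(died)),
            "mean_age_at_cancer_death": round(float(np.mean(ages_dd)), 2) if len(ages_dd) else np.nan,
            "min_age_at_cancer_death": round(float(np.min(ages_dd)), 2) if len(ages_dd) else np.nan,
            "max_age_at_cancer_death": round(float(np.max(ages_dd)), 2) if len(ages_dd) else np.nan,
        })
    return pd.DataFrame(rows)


def write_result(result: TrialResult, out_dir) -> None:
    """Write annual series, per-event tables, census and age summary."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.annual_series().to_csv(out / "annual_series.tsv", sep="\t", index=False)
    for name, tab in result.arm_tables.items():
        tab.to_csv(out / f"life_table_{name}.tsv", sep="\t", index=False)
    grid = []
    for t in np.linspace(0, result.design.horizon, 26):
        for name in result.arm_tables:
            c = census(result, float(t), arm=name)
            grid.append({"arm": name, "t": float(t), **c})
    pd.DataFrame(grid).to_csv(out / "census.tsv", sep="\t", index=False)
    summarize_ages(result).to_csv(out / "age_summary.tsv", sep="\t", index=False)
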