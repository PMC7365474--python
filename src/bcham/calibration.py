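"""Least-squares calibration of (b_b2, gamma, Z) to control-arm outcomes.

Three model parameters cannot be estimated from the literature: the
before-study detection constant ``b_b2``, the incidence scale ``gamma``
and the mortality diameter-exponent ``Z``.  They are chosen to minimize
the expected sum of squared deviations between simulated and recorded
control-arm outcome vectors (diagnosis and cancer-death counts).  Only the
control arm is ever simulated here; the mammography arm plays no role in
calibration.

The expected objective is smoothed with common random numbers: every
parameter vector is evaluated on the same set of simulation seeds, so the
surface seen by the optimizer is a deterministic function of theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._engine import simulate_eligible_cohort
from ._rng import StreamFactory
from .params import ModelParams
from .trial import TrialDesign, cnbss_design

__all__ = [
    "CalibrationTarget", "default_target_labels", "extract_control_outcomes",
    "make_synthetic_target", "objective", "expected_objective",
    "mean_outcome_objective", "calibrate",
]

DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float]] = {
    "b_b2": (20.0, 80.0),
    "gamma": (0.5, 3.0),
    "Z": (0.5, 2.0),
}


def default_target_labels(horizon: float = 25.0) -> list[str]:
    """Annual control diagnoses years 1-5, late diagnoses, total cancer deaths."""
    labels = [f"control_diagnoses_year_{y}" for y in range(1, 6)]
    labels.append(f"control_diagnoses_years_6_{int(horizon)}")
    labels.append(f"control_cancer_deaths_{int(horizon)}y")
    return labels


def extract_control_outcomes(life_table: pd.DataFrame, horizon: float = 25.0) -> np.ndarray:
    """Outcome vector of a *control-arm* life table matching the default labels."""
    if "arm" in life_table.columns and (life_table["arm"] != "control").any():
        raise ValueError("calibration extracts outcomes from the control arm only")
    det = life_table["detect_time"].to_numpy(float)
    out = [float(np.sum((det >= y - 1) & (det < y))) for y in range(1, 6)]
    out.append(float(np.sum((det >= 5) & (det < horizon))))
    out.append(float(np.sum(life_table["death_cause"].to_numpy() == "cancer")))
    return np.asarray(out)


@dataclass(frozen=True)
class CalibrationTarget:
    """Recorded outcome vector Y with the extractor that computes X.

    The extractor receives the simulated control-arm life table and must
    return a vector aligned with ``labels``.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    extractor: Callable[[pd.DataFrame], np.ndarray] = field(
        default=extract_control_outcomes)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.labels):
            raise ValueError("labels and values must have matching length")
        if np.any(v < 0):
            raise ValueError("target counts must be non-negative")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_table(cls, path) -> "CalibrationTarget":
        """Read a delimited (label, value) table."""
        tab = pd.read_csv(path, sep=None, engine="python")
        if tab.shape[1] < 2 or len(tab) == 0:
            raise ValueError("target table needs (label, value) rows")
        return cls(labels=tuple(tab.iloc[:, 0].astype(str)),
                   values=tab.iloc[:, 1].to_numpy(float))


def objective(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of squared deviations between matched outcome vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("outcome vectors must have identical shape")
    return float(np.sum((x - y) ** 2))


def _control_life_table(
    params: ModelParams, design: TrialDesign, n: int, seed: int
) -> pd.DataFrame:
    arm = design.arm("control")
    tab, _ = simulate_eligible_cohort(
        n, arm.bands, params, StreamFactory(seed), design.horizon,
        age_low=design.age_low, age_high=design.age_high)
    return tab


def expected_objective(
    theta: Mapping[str, float],
    target: CalibrationTarget,
    n_replicates: int,
    params: ModelParams,
    seed: int,
    design: TrialDesign | None = None,
    population: int = 5_000,
) -> tuple[float, float]:
    """Monte-Carlo estimate of E[S(theta)] with its standard error.

    Runs ``n_replicates`` control-arm simulations of ``population`` women
    at ``theta`` and averages the squared-deviation objective.  Replicate
    seeds are derived from ``seed`` alone, so two theta evaluated with the
    same seed share their random numbers.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    design = design or cnbss_design()
    p = params.with_(**dict(theta))
    streams = StreamFactory(seed)
    vals = np.empty(n_replicates)
    for r in range(n_replicates):
        tab = _control_life_table(p, design, population, streams.child_seed(r))
        vals[r] = objective(target.extractor(tab), target.values)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_replicates))


def mean_outcome_objective(
    theta: Mapping[str, float],
    target: CalibrationTarget,
    n_replicates: int,
    params: ModelParams,
    seed: int,
    design: TrialDesign | None = None,
    population: int = 5_000,
) -> float:
    """Squared distance of the replicate-averaged outcome vector to Y.

    Minimizing ``objective(mean(X), Y)`` rather than ``mean(objective(X, Y))``
    removes the parameter-dependent Monte-Carlo variance floor
    (E[S] = ||EX - Y||^2 + sum var(X_i)) that otherwise biases the argmin
    toward parameters producing fewer, less variable counts; both estimators
    share their minimum in expectation as the replicate count grows.
    """
    design = design or cnbss_design()
    p = params.with_(**dict(theta))
    streams = StreamFactory(seed)
    acc: np.ndarray | None = None
    for r in range(n_replicates):
        tab = _control_life_table(p, design, population, streams.child_seed(r))
        v = target.extractor(tab)
        acc = v if acc is None else acc + v
    return objective(acc / n_replicates, target.values)


def make_synthetic_target(
    theta: Mapping[str, float],
    params: ModelParams,
    seed: int,
    n_replicates: int = 20,
    design: TrialDesign | None = None,
    population: int = 5_000,
) -> CalibrationTarget:
    """Average control-arm outcome vector simulated at a known theta."""
    design = design or cnbss_design()
    p = params.with_(**dict(theta))
    streams = StreamFactory(seed)
    acc = None
    for r in range(n_replicates):
        tab = _control_life_table(p, design, population, streams.child_seed(r))
        v = extract_control_outcomes(tab, design.horizon)
        acc = v if acc is None else acc + v
    return CalibrationTarget(
        labels=tuple(default_target_labels(design.horizon)),
        values=acc / n_replicates)


def calibrate(
    target: CalibrationTarget,
    params: ModelParams,
    seed: int,
    search_space: Mapping[str, tuple[float, float]] | None = None,
    budget: int = 60,
    n_replicates: int = 20,
    n_replicates_grid: int | None = None,
    grid_points: int = 3,
    design: TrialDesign | None = None,
    population: int = 5_000,
) -> dict:
    """Grid search plus Nelder-Mead refinement of the smoothed objective.

    Minimizes :func:`mean_outcome_objective` (squared distance of the
    replicate-averaged outcome vector to the target).  ``budget`` caps the
    total number of objective evaluations (grid plus refinement); the
    coarse grid uses ``n_replicates_grid`` replicates (default: a quarter
    of ``n_replicates``) and the refinement the full ``n_replicates``,
    both with common random numbers across theta.  Returns the argmin, the
    sampled surface, and the evaluation counts.
    """
    search_space = dict(search_space or DEFAULT_SEARCH_SPACE)
    names = list(search_space)
    n_grid = grid_points ** len(names)
    if budget < n_grid + 1:
        raise ValueError(
            f"budget {budget} cannot cover the {n_grid}-point grid plus refinement")
    n_rep_grid = n_replicates_grid or max(2, n_replicates // 4)
    design = design or cnbss_design()

    surface: list[dict] = []
    evals = {"grid": 0, "refine": 0}

    def evaluate(theta_vec: np.ndarray, n_rep: int, stage: str) -> float:
        theta = {n: float(v) for n, v in zip(names, theta_vec)}
        for n, v in theta.items():
            lo, hi = search_space[n]
            if not lo <= v <= hi:
                # soft barrier keeps Nelder-Mead inside the box
                return 1e12 * (1.0 + float(np.sum(np.abs(theta_vec))))
        val = mean_outcome_objective(
            theta, target, n_rep, params, seed, design=design, population=population)
        surface.append({**theta, "objective": val, "stage": stage})
        evals[stage] += 1
        return val

    axes = [np.linspace(lo, hi, grid_points) for lo, hi in
            (search_space[n] for n in names)]
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(len(names), -1).T
    grid_vals = np.array([evaluate(g, n_rep_grid, "grid") for g in grid])
    x0 = grid[int(np.argmin(grid_vals))]

    # refine in box-normalized coordinates so Nelder-Mead steps are a fixed
    # fraction of each parameter's search range regardless of its units
    lo_v = np.array([search_space[n][0] for n in names])
    hi_v = np.array([search_space[n][1] for n in names])
    span = hi_v - lo_v
    z0 = (x0 - lo_v) / span
    simplex = [z0]
    for i in range(len(names)):
        step = np.zeros(len(names))
        step[i] = 0.2 if z0[i] <= 0.75 else -0.2
        simplex.append(np.clip(z0 + step, 0.0, 1.0))

    def run_nm(z_start: np.ndarray, maxfev: int):
        simplex = [z_start]
        for i in range(len(names)):
            step = np.zeros(len(names))
            step[i] = 0.2 if z_start[i] <= 0.75 else -0.2
            simplex.append(np.clip(z_start + step, 0.0, 1.0))
        return optimize.minimize(
            lambda z: evaluate(lo_v + span * np.clip(z, 0.0, 1.0),
                               n_replicates, "refine"),
            z_start, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 5e-3, "fatol": 1e-2,
                     "initial_simplex": np.array(simplex)})

    def eval_z(z: np.ndarray) -> float:
        return evaluate(lo_v + span * np.clip(z, 0.0, 1.0), n_replicates, "refine")

    # alternate Nelder-Mead with full-range coordinate sweeps: the sweeps
    # rescue parameters whose basin the simplex missed (a shallow direction
    # on the jagged common-random-number surface can strand a coordinate at
    # a box edge), the restarts polish the combined incumbent
    best_z, best_val = z0, np.inf
    budget_left = lambda: budget - n_grid - evals["refine"]  # noqa: E731
    improved = True
    while improved and budget_left() > 2 * len(names):
        improved = False
        res = run_nm(best_z, budget_left())
        if res.fun < best_val:
            best_z, best_val = np.clip(res.x, 0.0, 1.0), float(res.fun)
            improved = True
        if best_val == np.inf or budget_left() <= len(names):
            break
        for i in range(len(names)):
            if budget_left() < 7:
                break
            for zi in np.linspace(0.02, 0.98, 7):
                cand = best_z.copy()
                cand[i] = zi
                val = eval_z(cand)
                if val < best_val:
                    best_z, best_val = cand, val
                    improved = True

    best = {n: float(v) for n, v in zip(names, lo_v + span * best_z)}
    return {
        "theta": best,
        "objective": best_val,
        "surface": pd.DataFrame(surface),
        "n_evaluations": evals,
        "n_replicates": n_replicates,
        "search_space": {n: tuple(b) for n, b in search_space.items()},
        "population": population,
    }
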