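"""Benefit/harm analytics: arithmetic identities, statistical oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcham import natural_history as nh, outcomes as oc, simulator as sim
from bcham.params import ModelParams
from bcham.simulator import AgeBand, ScreeningSchedule


# ---------------------------------------------------------------------------
# subcohort classification


@pytest.mark.parametrize("k, d_max, onset, expected", [
    (0.02, 10.0, -2.0, (1, 1, "before_study")),
    (0.2, 120.0, 10.0, (6, 6, "after_study")),
    (0.05, 50.0, 2.0, (3, 3, "during_study")),
    # boundary values land in the lower class
    (0.0275, 22.36, 0.0, (1, 1, "during_study")),
])
def test_classify_subcohort(k, d_max, onset, expected):
    key = oc.classify_subcohort(k, d_max, onset)
    assert (key.k_sextile, key.d_max_sextile, key.onset_period) == expected


def test_classify_requires_onset():
    with pytest.raises(ValueError):
        oc.classify_subcohort(0.05, 50.0, float("nan"))


def test_k_boundary_consistent_with_lognormal_quantile():
    # analytic 1/6 quantile of lognormal(-2.9, 0.71) vs the published 0.0275
    q = np.exp(-2.9 + 0.71 * stats.norm.ppf(1.0 / 6.0))
    assert q == pytest.approx(0.0277, abs=2e-4)
    assert abs(q - oc.K_SEXTILE_BOUNDS[0]) / oc.K_SEXTILE_BOUNDS[0] < 0.05


def test_there_are_108_subcohorts():
    keys = {(k, d, p) for k in range(1, 7) for d in range(1, 7)
            for p in oc.ONSET_PERIODS}
    assert len(keys) == 108
    with pytest.raises(ValueError):
        oc.SubcohortKey(0, 1, "before_study")
    with pytest.raises(ValueError):
        oc.SubcohortKey(1, 1, "mid_study")


# ---------------------------------------------------------------------------
# excess incidence and chi-square


def test_excess_incidence_arithmetic():
    assert oc.excess_incidence(300, 1000, 250, 1000) == pytest.approx(50.0)
    assert oc.excess_incidence(30, 100, 30, 100) == 0.0
    assert oc.excess_incidence(250, 1000, 300, 1000) == pytest.approx(-50.0)
    with pytest.raises(ValueError):
        oc.excess_incidence(11, 10, 0, 10)


def test_chi_square_matches_textbook_formula():
    # 2x2 Pearson statistic computed from the classic closed form
    a, b, c, d = 30, 970, 10, 990  # diagnosed/not by arm
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat, p = oc.chi_square_diagnoses(30, 1000, 10, 1000)
    assert stat == pytest.approx(expected, rel=1e-12)
    stat_sw, _ = oc.chi_square_diagnoses(10, 1000, 30, 1000)
    assert stat_sw == pytest.approx(stat, rel=1e-12)


def test_chi_square_identical_proportions_is_zero():
    stat, p = oc.chi_square_diagnoses(25, 500, 25, 500)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_flags_zero_margin():
    stat, p = oc.chi_square_diagnoses(0, 100, 0, 100)
    assert np.isnan(stat) and np.isnan(p)


# ---------------------------------------------------------------------------
# Cox hazard ratio


def _six_records():
    return pd.DataFrame({
        "arm": ["mammography"] * 3 + ["control"] * 3,
        "onset_time": [0.0] * 6,
        "death_time": [4.0, 7.0, np.nan, 2.0, 3.5, 9.0],
        "censor_time": [10.0] * 6,
    })


def test_cox_matches_brute_force_partial_likelihood():
    records = _six_records()
    hr, p = oc.arm_hazard_ratio(records)

    # brute-force maximization of the Breslow partial likelihood on a grid
    death = records["death_time"].to_numpy()
    event = np.isfinite(death)
    time = np.where(event, death, 10.0)
    x = (records["arm"] == "mammography").to_numpy().astype(float)

    def log_pl(beta):
        ll = 0.0
        for i in np.where(event)[0]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return ll

    grid = np.linspace(-3, 3, 60001)
    beta_hat = grid[np.argmax([log_pl(b) for b in grid])]
    assert np.log(hr) == pytest.approx(beta_hat, abs=1e-3)


def test_cox_identical_arms_hr_near_one(rng):
    n = 400
    t = rng.exponential(5.0, n)
    records = pd.DataFrame({
        "arm": np.where(np.arange(n) % 2 == 0, "mammography", "control"),
        "onset_time": np.zeros(n),
        "death_time": np.where(t < 10.0, t, np.nan),
        "censor_time": np.full(n, 10.0),
    })
    hr, p = oc.arm_hazard_ratio(records)
    assert p > 0.01
    assert 0.7 < hr < 1.4


def test_cox_invariant_to_time_rescaling():
    records = _six_records()
    hr1, _ = oc.arm_hazard_ratio(records)
    scaled = records.copy()
    scaled["death_time"] *= 7.3
    scaled["censor_time"] *= 7.3
    hr2, _ = oc.arm_hazard_ratio(scaled)
    assert hr1 == pytest.approx(hr2, rel=1e-6)


def test_cox_undefined_without_events():
    records = _six_records()
    records["death_time"] = np.nan
    hr, p = oc.arm_hazard_ratio(records)
    assert np.isnan(hr) and np.isnan(p)


# ---------------------------------------------------------------------------
# overdiagnosis integral


def test_overdiagnosis_probability_is_one_without_cancer_hazard(params):
    # k -> 0 sends the cancer hazard to zero: death is certainly other-cause
    p = oc.overdiagnosis_probability(55.0, 10.0, 1e-9, params)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_overdiagnosis_probability_in_unit_interval(params, rng):
    for _ in range(25):
        age = rng.uniform(40, 80)
        d_de = rng.uniform(0.5, 100)
        k = rng.uniform(0.005, 0.4)
        p = oc.overdiagnosis_probability(age, d_de, k, params)
        assert 0.0 <= p <= 1.0


def test_overdiagnosis_matches_monte_carlo(params, rng):
    age, d_de, k, n = 55.0, 10.0, 0.03, 100_000
    p_quad = oc.overdiagnosis_probability(age, d_de, k, params)
    t_other = nh.sample_other_cause_death(
        np.full(n, age), rng.uniform(size=n), params)
    t_cancer = nh.sample_cancer_death_time(
        np.full(n, d_de), np.full(n, k), rng.uniform(size=n), params,
        alpha=oc.OVERDIAGNOSIS_ALPHA)
    p_mc = float(np.mean(t_other < t_cancer))
    se = np.sqrt(p_mc * (1 - p_mc) / n)
    assert abs(p_quad - p_mc) < 3 * se


def test_vectorized_overdiagnosis_agrees_with_adaptive_quadrature(params):
    records = pd.DataFrame({
        "age_at_enroll": [45.0, 52.0, 58.0],
        "detect_time": [1.0, 3.0, 0.0],
        "detect_diameter": [8.0, 25.0, 60.0],
        "k": [0.02, 0.07, 0.2],
    })
    fast = oc.overdiagnosis_probabilities(records, params)
    slow = [oc.overdiagnosis_probability(
        a + t, d, k, params) for a, t, d, k in zip(
        records["age_at_enroll"], records["detect_time"],
        records["detect_diameter"], records["k"])]
    assert np.allclose(fast, slow, atol=1e-6)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_degenerate_metric(rng):
    records = pd.DataFrame({"id": np.repeat(np.arange(20), 3),
                            "value": np.ones(60)})
    lo, hi = oc.bootstrap_ci(lambda df: 1.0, records, n_boot=50, seed=1)
    assert lo == hi == 1.0


def test_bootstrap_interval_width_scales_inverse_sqrt(rng):
    widths = []
    for n in (250, 1000, 4000):
        records = pd.DataFrame({"id": np.arange(n),
                                "value": rng.normal(0.0, 1.0, n)})
        lo, hi = oc.bootstrap_ci(
            lambda df: float(df["value"].mean()), records, n_boot=200, seed=n)
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]
    # quadrupling n should halve the width, within bootstrap noise
    assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)
    assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.35)


def test_bootstrap_requires_replicates():
    records = pd.DataFrame({"id": [0, 1], "value": [1.0, 2.0]})
    with pytest.raises(ValueError):
        oc.bootstrap_ci(lambda df: 0.0, records, n_boot=1)


# ---------------------------------------------------------------------------
# scenarios and paired benefit


def test_high_risk_multiplies_incidence(params, rng):
    hr = oc.scenario_high_risk(params)
    assert hr.incidence_multiplier == 5.0
    # rare-event regime: onsets scale linearly with the multiplier
    base = params.with_(gamma=0.05)
    n = 200_000
    e = rng.exponential(size=n)
    t1 = nh.inverse_cumulative_incidence(45.0, 0.0, e, base)
    t5 = nh.inverse_cumulative_incidence(45.0, 0.0, e, oc.scenario_high_risk(base))
    n1 = float(np.sum(np.asarray(t1) < 25.0))
    n5 = float(np.sum(np.asarray(t5) < 25.0))
    se = np.sqrt(5 * n1)
    assert abs(n5 - 5 * n1) < 3 * se


def test_identity_multiplier_changes_nothing(params):
    assert params.with_(incidence_multiplier=1.0) == params


def test_survival_benefit_zero_for_identical_schedules(params):
    bands = (AgeBand(40.0, 60.0, ScreeningSchedule(
        mammography_times=(0.0, 1.0, 2.0))),)
    arm_bands = {"mammography": bands, "control": bands}
    pats = sim.sample_cancer_patients(4000, params, seed=51, horizon=10.0)
    paired = sim.simulate_paired_cohort(pats, arm_bands, 2, params, seed=52,
                                        horizon=10.0)
    benefit = oc.survival_benefit(paired, horizon=10.0)
    assert abs(benefit) < 1.0  # percentage points, paired Monte-Carlo noise


def test_subcohort_summary_schema(params):
    design_bands = {
        "mammography": (AgeBand(40.0, 60.0, ScreeningSchedule(
            mammography_times=(0.0, 1.0, 2.0, 3.0, 4.0),
            physical_times=(0.0, 1.0, 2.0, 3.0, 4.0))),),
        "control": (AgeBand(40.0, 60.0, ScreeningSchedule()),),
    }
    pats = sim.sample_cancer_patients(3000, params, seed=61, horizon=25.0)
    paired = sim.simulate_paired_cohort(pats, design_bands, 2, params, seed=62)
    grid = oc.subcohort_summary(paired, params, n_boot=0)
    assert len(grid) <= 108
    assert grid["k_sextile"].between(1, 6).all()
    assert grid["d_max_sextile"].between(1, 6).all()
    assert set(grid["onset_period"]) <= set(oc.ONSET_PERIODS)
    assert grid["diag_diff_per_1000"].between(-1000, 1000).all()
    hr = grid["hazard_ratio"].dropna()
    assert (hr > 0).all()
    # mammography can only add detection channels: its diagnosis fraction is
    # no lower than the control's, up to Monte-Carlo noise on the proportions
    el = paired[paired["eligible"]]
    dx = el.groupby("arm")["detect_time"].apply(lambda s: np.isfinite(s).mean())
    n_per_arm = (el["arm"] == "control").sum()
    noise = 3.0 * np.sqrt(2.0 * 0.25 / n_per_arm)
    assert dx["mammography"] >= dx["control"] - noise
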