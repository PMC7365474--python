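"""Life-course engine: exactness of the samplers and composition invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from bcham import _engine, natural_history as nh, simulator as sim
from bcham.params import ModelParams
from bcham.population import EnrollmentState, Individual
from bcham.simulator import ScreeningSchedule

NO_MORT = 1e-300  # numerically disables the other-cause hazard


def _individual(age=45.0, k=0.1, d_max=50.0, ident=0):
    return Individual(id=ident, age_at_enroll=age, k=k, d_max=d_max, seed=0)


# ---------------------------------------------------------------------------
# Stage 1: exact first-event sampling vs a literal daily-thinning oracle


def test_stage1_no_rates_no_events(params, rng):
    p = params.with_(gamma=0.0, mort_c0=NO_MORT)
    for _ in range(20):
        kind, t = sim.sample_onset(50.0, 25.0, p, rng)
        assert kind is None and t is None


def _daily_law(age, horizon, params, dt_days=1.0):
    """Exact law of the daily Bernoulli-thinning scheme for stage 1.

    Returns per-day times and the probabilities of (onset at day j),
    (death at day j), evaluated exactly; onset is evaluated before death
    within a day.
    """
    dt = dt_days / 365.25
    edges = np.arange(0.0, horizon + dt, dt)
    mids = edges[:-1] + dt / 2.0
    p_on = 1.0 - np.exp(-nh.incidence_rate(age, mids, params) * dt)
    p_de = 1.0 - np.exp(-nh.other_cause_hazard(age, mids, params) * dt)
    surv = np.concatenate([[1.0], np.cumprod((1.0 - p_on) * (1.0 - p_de))])[:-1]
    return mids, surv * p_on, surv * (1.0 - p_on) * p_de


def test_stage1_sampler_matches_daily_thinning_oracle(params, rng):
    age, horizon, n = 45.0, 10.0, 100_000
    e = rng.exponential(size=n)
    t_on = np.atleast_1d(nh.inverse_cumulative_incidence(age, 0.0, e, params))
    t_de = np.atleast_1d(nh.sample_other_cause_death(
        age, rng.uniform(size=n), params))
    engine_onsets = t_on[(t_on < t_de) & (t_on < horizon)]

    mids, p_onset, p_death = _daily_law(age, horizon, params)
    probs = np.concatenate([p_onset, [1.0 - p_onset.sum()]])
    draw = rng.choice(mids.size + 1, size=n, p=probs / probs.sum())
    oracle_onsets = mids[draw[draw < mids.size]]

    # onset frequency agrees
    f_eng = engine_onsets.size / n
    f_orc = oracle_onsets.size / n
    se = np.sqrt(2 * f_orc * (1 - f_orc) / n)
    assert abs(f_eng - f_orc) < 3 * se
    # conditional onset-time distribution agrees
    res = stats.ks_2samp(engine_onsets, oracle_onsets)
    assert res.pvalue > 0.01


def test_stage1_event_split_matches_competing_risks_quadrature(params, rng):
    age, horizon, n = 52.0, 15.0, 100_000
    e = rng.exponential(size=n)
    t_on = np.atleast_1d(nh.inverse_cumulative_incidence(age, 0.0, e, params))
    t_de = np.atleast_1d(nh.sample_other_cause_death(age, rng.uniform(size=n), params))
    p_hat = float(np.mean((t_on < t_de) & (t_on < horizon)))

    def integrand(t):
        return (nh.incidence_rate(age, t, params)
                * np.exp(-nh.cumulative_incidence(age, 0.0, t, params)
                         - nh.other_cause_cumulative(age, 0.0, t, params)))

    p_true, _ = integrate.quad(integrand, 0.0, horizon)
    se = np.sqrt(p_true * (1 - p_true) / n)
    assert abs(p_hat - p_true) < 3 * se


# ---------------------------------------------------------------------------
# Stage 2: detection at scheduled exams


def test_certain_detection_at_first_exam(params, rng):
    p = params.with_(b_m2=1e-9, mort_c0=NO_MORT, self_exams_per_year=0.0)
    sched = ScreeningSchedule(mammography_times=(1.0 / 365.25,))
    kind, t, d_de, modality = sim.simulate_undetected_phase(
        0.0, _individual(), sched, p, rng, horizon=5.0)
    assert kind == "detected" and modality == "mammography"
    assert t == pytest.approx(1.0 / 365.25)
    months = t * 12.0
    assert d_de == pytest.approx(
        float(nh.gompertz_diameter(months, p.d0, 50.0, 0.1)), rel=1e-9)


def test_no_sensitivity_no_mortality_censors(params, rng):
    p = params.with_(b_m2=1e9, b_p2=1e9, b_s2=1e9, mort_c0=NO_MORT)
    sched = ScreeningSchedule(mammography_times=(0.0, 1.0), physical_times=(0.0,))
    kind, t, _, _ = sim.simulate_undetected_phase(
        0.0, _individual(), sched, p, rng, horizon=25.0)
    assert kind == "censored" and t == 25.0


def test_detection_year_histogram_matches_bernoulli_oracle(params, rng):
    # single annual mammography, self exams off, mortality off
    p = params.with_(mort_c0=NO_MORT, self_exams_per_year=0.0)
    years = tuple(float(y) for y in range(10))
    sched = ScreeningSchedule(mammography_times=years)
    ind = _individual(k=0.1, d_max=50.0)
    onset = -1e-4  # just before the entry exam, so every exam sees the tumor
    n = 4000
    got = np.full(n, -1)
    for i in range(n):
        kind, t, _, _ = sim.simulate_undetected_phase(
            onset, ind, sched, p, rng, horizon=10.0)
        if kind == "detected":
            got[i] = int(round(t))
    # per-exam Bernoulli oracle built from the growth law and S_m
    diam = nh.gompertz_diameter((np.array(years) - onset) * 12.0, p.d0, 50.0, 0.1)
    pj = nh.detection_sensitivity(diam, "mammography", p)
    none = np.prod(1.0 - pj)
    probs = np.array([pj[j] * np.prod(1.0 - pj[:j]) for j in range(len(years))])
    counts = np.array([(got == j).sum() for j in range(len(years))] + [(got == -1).sum()])
    expected = n * np.concatenate([probs, [none]])
    keep = expected > 5
    res = stats.chisquare(counts[keep], expected[keep] * counts[keep].sum()
                          / expected[keep].sum())
    assert res.pvalue > 0.01


# ---------------------------------------------------------------------------
# Stage 3: exact Weibull sampling and competing risks


def test_huge_alpha_means_no_cancer_death(params, rng):
    out, t = sim.simulate_detected_phase(
        (1.0, 15.0, "mammography"), _individual(k=0.5), params, rng,
        horizon=25.0, alpha=200.0)
    assert out in ("other", "censored")


def test_five_year_cancer_survival_matches_closed_form(params, rng):
    p = params.with_(mort_c0=NO_MORT)
    d_de, k, n = 15.0, 0.0708, 20_000
    ind = _individual(k=k)
    alive = 0
    for _ in range(n):
        out, t = sim.simulate_detected_phase((0.0, d_de, "self"), ind, p, rng,
                                             horizon=25.0)
        alive += out == "censored" or t >= 5.0
    rate = k**p.alpha_eff * d_de**p.Z
    s5 = np.exp(-rate * 5.0**p.omega)
    se = np.sqrt(s5 * (1 - s5) / n)
    assert abs(alive / n - s5) < 3 * se


def test_cause_of_death_split_matches_quadrature(params, rng):
    d_de, k, age, t_d = 20.0, 0.15, 55.0, 0.0
    n = 20_000
    cancer = 0
    ind = _individual(age=age, k=k)
    for _ in range(n):
        out, _ = sim.simulate_detected_phase((t_d, d_de, "self"), ind, params, rng,
                                             horizon=1e6)
        cancer += out == "cancer"
    rate = k**params.alpha_eff * d_de**params.Z

    def integrand(tau):
        hc = rate * params.omega * tau ** (params.omega - 1.0)
        return hc * np.exp(-rate * tau**params.omega
                           - nh.other_cause_cumulative(age, 0.0, tau, params))

    p_cancer, _ = integrate.quad(integrand, 0.0, 80.0)
    se = np.sqrt(p_cancer * (1 - p_cancer) / n)
    assert abs(cancer / n - p_cancer) < 3 * se


# ---------------------------------------------------------------------------
# composition


def test_healthy_course_without_incidence(params, rng):
    p = params.with_(gamma=0.0)
    lc = sim.simulate_individual(
        _individual(), EnrollmentState(status="healthy"),
        ScreeningSchedule(mammography_times=(0.0,)), p, rng)
    assert lc.onset_time is None and lc.detection is None
    if lc.death is not None:
        assert lc.death[1] == "other"


def test_prevalent_cancer_detected_at_entry_screen(params, rng):
    p = params.with_(b_m2=1e-9, mort_c0=NO_MORT)
    state = EnrollmentState(status="undetected_cancer", onset_time=-3.0,
                            diameter_at_enroll=12.0)
    lc = sim.simulate_individual(
        _individual(), state, ScreeningSchedule(mammography_times=(0.0, 1.0)),
        p, rng)
    assert lc.detection is not None
    assert lc.detection[0] == 0.0 and lc.detection[2] == "mammography"


def test_life_course_validates_event_ordering():
    with pytest.raises(ValueError):
        sim.LifeCourse(0, onset_time=None, detection=(1.0, 5.0, "self"))
    with pytest.raises(ValueError):
        sim.LifeCourse(0, onset_time=0.0, detection=(2.0, 5.0, "self"),
                       death=(1.0, "cancer"))


def test_stage_occupancy_partitions(params, rng):
    lc = sim.LifeCourse(0, onset_time=1.0, detection=(3.0, 8.0, "self"),
                        death=(7.0, "cancer"), censor_time=25.0)
    assert [lc.stage_at(t) for t in (0.5, 2.0, 5.0, 10.0)] == [
        "healthy", "undetected", "detected", "cancer_death"]


def test_fuzzed_life_tables_satisfy_invariants(params):
    from bcham._rng import StreamFactory

    bands = (sim.AgeBand(40.0, 60.0, ScreeningSchedule(
        mammography_times=(0.0, 1.0, 2.0, 3.0, 4.0),
        physical_times=(0.0, 1.0, 2.0, 3.0, 4.0))),)
    tab = _engine.simulate_batch(
        StreamFactory(99), (), 0, 50_000, bands, params, 25.0, 40.0, 59.0)
    onset = tab["onset_time"].to_numpy(float)
    det = tab["detect_time"].to_numpy(float)
    death = tab["death_time"].to_numpy(float)
    cause = tab["death_cause"].to_numpy()
    has_det = np.isfinite(det)
    # detection requires onset, strictly before it
    assert np.all(np.isfinite(onset[has_det]))
    assert np.all(onset[has_det] < det[has_det])
    # cancer death requires detection and follows it
    cdeath = cause == "cancer"
    assert np.all(has_det[cdeath])
    assert np.all(death[cdeath] > det[cdeath])
    # the enrollment partition is exhaustive and exclusive
    assert set(tab["status_at_enroll"]) <= {"healthy", "undetected_cancer", "ineligible"}
    assert np.all(tab["eligible"] == (tab["status_at_enroll"] != "ineligible"))
    # deaths and censoring never coexist
    died = np.isfinite(death)
    assert np.all(death[died] < tab["censor_time"].to_numpy(float)[died])


# ---------------------------------------------------------------------------
# paired replicates


def test_paired_onsets_shared_across_arms(params):
    design_bands = {
        "mammography": (sim.AgeBand(40.0, 60.0, ScreeningSchedule(
            mammography_times=(0.0, 1.0))),),
        "control": (sim.AgeBand(40.0, 60.0, ScreeningSchedule()),),
    }
    pats = sim.sample_cancer_patients(500, params, seed=21, horizon=10.0)
    paired = sim.simulate_paired_cohort(pats, design_bands, 3, params, seed=22,
                                        horizon=10.0)
    wide = paired.pivot_table(index=["id", "pair"], columns="arm",
                              values="onset_time")
    assert np.allclose(wide["mammography"], wide["control"])
    # the shared other-cause clock also matches whenever neither arm's course
    # was altered by a cancer death
    other = paired[paired["death_cause"] != "cancer"].pivot_table(
        index=["id", "pair"], columns="arm", values="death_time").dropna()
    assert np.allclose(other["mammography"], other["control"])


def test_paired_cohort_deterministic(params):
    bands = {"mammography": (sim.AgeBand(40.0, 60.0, ScreeningSchedule(
        mammography_times=(0.0,))),),
        "control": (sim.AgeBand(40.0, 60.0, ScreeningSchedule()),)}
    pats = sim.sample_cancer_patients(300, params, seed=5, horizon=5.0)
    a = sim.simulate_paired_cohort(pats, bands, 2, params, seed=6, horizon=5.0)
    b = sim.simulate_paired_cohort(pats, bands, 2, params, seed=6, horizon=5.0)
    assert a.equals(b)


def test_paired_design_reduces_variance(params):
    """Common random numbers: the paired benefit estimator has no larger
    variance than the same estimator on independent cohorts."""
    bands = {
        "mammography": (sim.AgeBand(40.0, 60.0, ScreeningSchedule(
            mammography_times=(0.0, 1.0, 2.0, 3.0, 4.0))),),
        "control": (sim.AgeBand(40.0, 60.0, ScreeningSchedule()),),
    }
    n, reps, horizon = 1000, 25, 10.0

    def benefit(df):
        el = df[df["eligible"]]
        alive = ~(np.isfinite(el["death_time"].to_numpy(float)))
        m = alive[(el["arm"] == "mammography").to_numpy()].mean()
        c = alive[(el["arm"] == "control").to_numpy()].mean()
        return m - c

    paired_vals, indep_vals = [], []
    for r in range(reps):
        pats = sim.sample_cancer_patients(n, params, seed=1000 + r, horizon=horizon)
        paired_vals.append(benefit(sim.simulate_paired_cohort(
            pats, bands, 1, params, seed=2000 + r, horizon=horizon)))
        pats2 = sim.sample_cancer_patients(n, params, seed=3000 + r, horizon=horizon)
        dm = sim.simulate_paired_cohort(pats, bands, 1, params, seed=4000 + r,
                                        horizon=horizon)
        dc = sim.simulate_paired_cohort(pats2, bands, 1, params, seed=5000 + r,
                                        horizon=horizon)
        indep = pd.concat([dm[dm["arm"] == "mammography"],
                           dc[dc["arm"] == "control"]], ignore_index=True)
        indep_vals.append(benefit(indep))
    assert np.var(paired_vals) <= 1.5 * np.var(indep_vals)


def test_scalar_paired_replicates_contract(params, rng):
    schedules = {
        "mammography": ScreeningSchedule(mammography_times=(0.0, 1.0)),
        "control": ScreeningSchedule(),
    }
    ind = _individual(k=0.08, d_max=80.0)
    state = EnrollmentState(status="undetected_cancer", onset_time=-2.0,
                            diameter_at_enroll=5.0)
    out = sim.run_paired_replicates(ind, state, schedules, 5, params, seed=17)
    assert set(out) == {"mammography", "control"}
    assert len(out["mammography"]) == len(out["control"]) == 5
    for lc_m, lc_c in zip(out["mammography"], out["control"]):
        assert lc_m.onset_time == lc_c.onset_time == -2.0
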