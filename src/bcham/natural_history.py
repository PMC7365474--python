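"""Natural-history primitives: growth law, rates, sensitivities, hazards.

Every function is a pure, numpy-vectorized evaluation of one of the model's
building blocks, together with its closed-form cumulative and inverse where
one exists:

* Gompertz tumor growth on the diameter scale,
* the bell-shaped (Gaussian) age-specific cancer incidence rate,
* the exponential other-cause mortality rate,
* logistic size-dependent detection sensitivities per modality,
* the Weibull post-detection cancer-mortality hazard.

Time arguments follow the model's unit conventions (see :mod:`bcham.params`):
``elapsed`` in the growth law is months (the aggressiveness k is per
month); incidence, other-cause mortality, and the post-detection
mortality-hazard clock ``tau`` are years.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .params import ModelParams, derived_alpha, derived_k_mean  # noqa: F401

__all__ = [
    "gompertz_diameter",
    "incidence_rate",
    "cumulative_incidence",
    "inverse_cumulative_incidence",
    "other_cause_hazard",
    "other_cause_cumulative",
    "sample_other_cause_death",
    "detection_sensitivity",
    "cancer_mortality_hazard",
    "cancer_death_cumulative_hazard",
    "cancer_death_survival",
    "sample_cancer_death_time",
    "derived_alpha",
    "derived_k_mean",
]


def gompertz_diameter(elapsed, d_ini, d_max, k, exponent_factor: float = 1.0):
    """Tumor diameter (mm) after ``elapsed`` months of Gompertz growth.

    d(t) = d_max * (d_ini / d_max) ** exp(-f * k * elapsed)

    with aggressiveness ``k`` (month^-1) and asymptote ``d_max``.  With the
    default f = 1 this is the growth law exp(-12 k (t - t0)) for t in
    years.  Strictly increasing in ``elapsed`` and bounded above by
    ``d_max``.
    """
    elapsed = np.asarray(elapsed, dtype=float)
    d_ini = np.asarray(d_ini, dtype=float)
    d_max = np.asarray(d_max, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed must be non-negative")
    if np.any(d_ini <= 0) or np.any(d_max <= 0) or np.any(k <= 0):
        raise ValueError("d_ini, d_max and k must be positive")
    if np.any(d_ini > d_max):
        raise ValueError("d_ini must not exceed d_max")
    expo = np.exp(-exponent_factor * k * elapsed)
    out = d_max * (d_ini / d_max) ** expo
    return out if out.ndim else float(out)


def incidence_rate(age_at_enroll, t, params: ModelParams):
    """Cancer incidence rate c_a(t) in 1/year at age ``age_at_enroll + t``.

    A Gaussian bell in attained age, scaled by the lifetime mass 0.1967, the
    fitted factor gamma, and the scenario incidence multiplier.
    """
    a = np.asarray(age_at_enroll, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(a + t < 0):
        raise ValueError("attained age must be non-negative")
    scale = (
        params.incidence_multiplier
        * params.incidence_mass
        * params.gamma
        / (params.sigma_age * np.sqrt(2.0 * np.pi))
    )
    z = (t + a - params.mu_age) / params.sigma_age
    out = scale * np.exp(-0.5 * z**2)
    return out if out.ndim else float(out)


def _incidence_total_mass(params: ModelParams) -> float:
    return params.incidence_multiplier * params.incidence_mass * params.gamma


def cumulative_incidence(age_at_enroll, t1, t2, params: ModelParams):
    """Exact integral of the incidence rate over [t1, t2] (Gaussian CDF form)."""
    a = np.asarray(age_at_enroll, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 > t2):
        raise ValueError("t1 must be <= t2")
    mass = _incidence_total_mass(params)
    z1 = (a + t1 - params.mu_age) / params.sigma_age
    z2 = (a + t2 - params.mu_age) / params.sigma_age
    out = mass * (special.ndtr(z2) - special.ndtr(z1))
    return out if out.ndim else float(out)


def inverse_cumulative_incidence(age_at_enroll, t_start, exp_draw, params: ModelParams):
    """Onset time t with cumulative incidence from ``t_start`` equal to the draw.

    Solves ``cumulative_incidence(a, t_start, t) == exp_draw`` for ``t``
    analytically via the Gaussian quantile.  Returns ``+inf`` where the draw
    exceeds the remaining incidence mass (no onset, ever).
    """
    a = np.asarray(age_at_enroll, dtype=float)
    t_start = np.asarray(t_start, dtype=float)
    e = np.asarray(exp_draw, dtype=float)
    mass = _incidence_total_mass(params)
    if mass == 0.0:
        out = np.full(np.broadcast(a, t_start, e).shape, np.inf)
        return out if out.ndim else float(out)
    z1 = (a + t_start - params.mu_age) / params.sigma_age
    target = special.ndtr(z1) + e / mass
    with np.errstate(invalid="ignore"):
        t = params.mu_age - a + params.sigma_age * special.ndtri(target)
    out = np.where(target >= 1.0, np.inf, t)
    return out if np.ndim(out) else float(out)


def other_cause_hazard(age_at_enroll, t, params: ModelParams):
    """Other-cause mortality rate h_a(t) = c0 * exp(c1 * (t + a)), 1/year."""
    a = np.asarray(age_at_enroll, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(a + t < 0):
        raise ValueError("attained age must be non-negative")
    out = params.mort_c0 * np.exp(params.mort_c1 * (t + a))
    return out if out.ndim else float(out)


def other_cause_cumulative(age_at_enroll, t1, t2, params: ModelParams):
    """Integral of the other-cause rate over [t1, t2] (closed form)."""
    a = np.asarray(age_at_enroll, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t1 > t2):
        raise ValueError("t1 must be <= t2")
    c0, c1 = params.mort_c0, params.mort_c1
    out = (c0 / c1) * (np.exp(c1 * (a + t2)) - np.exp(c1 * (a + t1)))
    return out if out.ndim else float(out)


def sample_other_cause_death(age_at_enroll, u, params: ModelParams, t_start=0.0):
    """Exact inverse-CDF draw of the other-cause death time (years from t=0).

    Inverts -log(u) = integral of h_a from ``t_start`` to T, conditional on
    being alive at ``t_start``.  Exact: no discretization.
    """
    a = np.asarray(age_at_enroll, dtype=float)
    u = np.asarray(u, dtype=float)
    t_start = np.asarray(t_start, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly inside (0, 1)")
    c0, c1 = params.mort_c0, params.mort_c1
    e = -np.log(u)
    out = np.log(np.exp(c1 * (a + t_start)) + c1 * e / c0) / c1 - a
    return out if out.ndim else float(out)


_MODALITY_FIELD = {
    "before_study": "b_b2",
    "mammography": "b_m2",
    "physical": "b_p2",
    "self": "b_s2",
}


def detection_sensitivity(d, modality: str, params: ModelParams):
    """Probability that one exam of the given modality detects a tumor of size d.

    Logistic in diameter: S_j(d) = expit((d - b_j2) / b1), with per-modality
    half-detection diameter b_j2.  Strictly increasing in d, valued in (0,1).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    try:
        b2 = getattr(params, _MODALITY_FIELD[modality])
    except KeyError:
        raise ValueError(
            f"unknown modality {modality!r}; expected one of {sorted(_MODALITY_FIELD)}"
        ) from None
    out = special.expit((d - b2) / params.b1)
    return out if out.ndim else float(out)


def cancer_mortality_hazard(d_de, k, tau, params: ModelParams, alpha: float | None = None):
    """Post-detection cancer-mortality hazard (1/year).

    h(d_de, k, tau) = k^alpha * d_de^Z * omega * tau^(omega-1) with ``tau``
    years since detection.  Larger alpha with k < 1 means more effective
    treatment (lower hazard).
    """
    d_de = np.asarray(d_de, dtype=float)
    k = np.asarray(k, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(d_de <= 0) or np.any(k <= 0):
        raise ValueError("d_de and k must be positive")
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    a = params.alpha_eff if alpha is None else float(alpha)
    if a <= 0:
        raise ValueError("alpha must be positive")
    om = params.omega
    with np.errstate(divide="ignore"):
        tpow = np.where(tau > 0, tau ** (om - 1.0), np.inf if om < 1 else (1.0 if om == 1 else 0.0))
    out = k**a * d_de**params.Z * om * tpow
    return out if np.ndim(out) else float(out)


def cancer_death_cumulative_hazard(d_de, k, tau, params: ModelParams, alpha: float | None = None):
    """Integral of the cancer-mortality hazard from detection: k^a d^Z tau^omega."""
    d_de = np.asarray(d_de, dtype=float)
    k = np.asarray(k, dtype=float)
    tau = np.asarray(tau, dtype=float)
    a = params.alpha_eff if alpha is None else float(alpha)
    out = k**a * d_de**params.Z * tau**params.omega
    return out if out.ndim else float(out)


def cancer_death_survival(d_de, k, tau, params: ModelParams, alpha: float | None = None):
    """Probability of surviving the cancer hazard tau years past detection.

    Two-parameter Weibull survival exp(-k^alpha * d_de^Z * tau^omega).
    """
    out = np.exp(-cancer_death_cumulative_hazard(d_de, k, tau, params, alpha))
    return out if np.ndim(out) else float(out)


def sample_cancer_death_time(d_de, k, u, params: ModelParams, alpha: float | None = None):
    """Exact Weibull inverse draw of years from detection to cancer death."""
    d_de = np.asarray(d_de, dtype=float)
    k = np.asarray(k, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly inside (0, 1)")
    a = params.alpha_eff if alpha is None else float(alpha)
    rate = k**a * d_de**params.Z
    out = (-np.log(u) / rate) ** (1.0 / params.omega)
    return out if out.ndim else float(out)
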