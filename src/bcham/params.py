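"""Model parameters for the breast-cancer heterogeneity/aggressiveness model.

All natural-history constants live in a single flat :class:`ModelParams`
record.  Defaults reproduce the published calibration of the model to the
Canadian National Breast Screening Study (CNBSS): three parameters
(``b_b2``, ``gamma``, ``Z``) were fitted to the control arm of that trial,
everything else comes from the literature.

Unit conventions
----------------
Tumor diameters are millimetres.  The aggressiveness constant ``k`` is per
month and enters the year-scale growth law through an explicit factor of
12; cancer incidence, other-cause mortality, and the post-detection
cancer-mortality hazard all run on a *year* time scale.  Conversion
helpers are exported as module constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

MONTHS_PER_YEAR = 12.0
DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375

#: Reference tumor diameter (mm) appearing in the closed-form definition of
#: the treatment-effectiveness exponent alpha.  A named literal, not a free
#: parameter.
REF_DIAMETER_MM = 15.0

MODALITIES = ("before_study", "mammography", "physical", "self")


def derived_k_mean(mu_k: float, sigma_k: float) -> float:
    """Mean of a lognormal aggressiveness: k_m = exp(mu_k + sigma_k^2 / 2)."""
    return math.exp(mu_k + sigma_k**2 / 2.0)


def derived_alpha(Q: float, omega: float, k_m: float) -> float:
    """Default treatment-effectiveness exponent.

    alpha = log(Q / 15^omega) / log(k_m); the ratio of logs is base
    invariant.  Requires 0 < Q < 1 and 0 < k_m < 1 (k_m = 1 would put a
    zero in the denominator).
    """
    if not 0.0 < Q < 1.0:
        raise ValueError(f"Q must be in (0, 1), got {Q}")
    if not 0.0 < k_m < 1.0:
        raise ValueError(f"k_m must be in (0, 1), got {k_m}")
    if omega <= 0.0:
        raise ValueError(f"omega must be positive, got {omega}")
    return math.log(Q / REF_DIAMETER_MM**omega) / math.log(k_m)


@dataclass(frozen=True)
class ModelParams:
    """Flat record of every natural-history constant.

    Attributes
    ----------
    Q : float
        Cancer-mortality hazard scale (1/mm^Z).
    Z : float
        Diameter exponent in the cancer-mortality hazard (estimated from the
        CNBSS control arm).
    omega : float
        Weibull shape of the post-detection mortality hazard.
    gamma : float
        Scale factor of the cancer-incidence rate (estimated).
    mu_age, sigma_age : float
        Peak age and spread (years) of the bell-shaped incidence rate.
    incidence_mass : float
        Lifetime incidence mass constant 0.1967 (opaque registry constant).
    mort_c0, mort_c1 : float
        Other-cause mortality rate c0*exp(c1*age), in 1/year.
    b1 : float
        Detection-sensitivity slope (mm).
    b_m2, b_p2, b_s2, b_b2 : float
        Half-detection diameters (mm) for mammography, physical exam,
        self exam, and the before-study self exam.
    d0 : float
        Diameter of a single cell (mm); every tumor starts here.
    mu_k, sigma_k : float
        Mean and sd of log aggressiveness (log month^-1 scale).
    alpha : float or None
        Treatment-effectiveness exponent; ``None`` means "derive the
        default 3.19 from (Q, omega, k_m)".
    incidence_multiplier : float
        Scenario factor on the incidence rate (1 = baseline, 5 = high risk).
    growth_exponent_factor : float
        Factor multiplying k (month^-1) on the month-scale growth clock.
        The default 1.0 is the literal growth law exp(-12 k (t - t0)) with
        t in years; 0.5 gives the alternative half-rate reading.
    d_max_low, d_max_high : float
        Support of the uniform maximum-diameter distribution (mm).
    burn_in_years : float
        Pre-study burn-in window during which prevalent cancers accrue.
    before_study_exams_per_year : float
        Cadence of the before-study self checks during burn-in (annual:
        a coarse eligibility screen for noticeable tumors).
    self_exams_per_year : float
        Cadence of in-study self exams (both arms, whole follow-up).  This
        is the only non-screen detection channel; its biweekly default is
        the effective symptomatic-surfacing rate that best reproduces the
        recorded control-arm outcomes of the calibration trial.
    detection_before_death_same_day : bool
        Within-day tie rule: on an exam day, evaluate detection before
        other-cause death.
    """

    Q: float = 0.0067
    Z: float = 1.06
    omega: float = 1.272
    gamma: float = 1.54
    mu_age: float = 76.86
    sigma_age: float = 19.5
    incidence_mass: float = 0.1967
    mort_c0: float = 0.208e-5
    mort_c1: float = 0.1196
    b1: float = 1.5
    b_m2: float = 6.33
    b_p2: float = 18.5
    b_s2: float = 20.0
    b_b2: float = 40.0
    d0: float = 0.0124
    mu_k: float = -2.9
    sigma_k: float = 0.71
    alpha: float | None = None
    incidence_multiplier: float = 1.0
    growth_exponent_factor: float = 1.0
    d_max_low: float = 1.0
    d_max_high: float = 128.0
    burn_in_years: float = 6.0
    before_study_exams_per_year: float = 1.0
    self_exams_per_year: float = 26.0
    detection_before_death_same_day: bool = True

    def __post_init__(self) -> None:
        for name in ("b_m2", "b_p2", "b_s2", "b_b2", "d0", "b1",
                     "d_max_low", "d_max_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma_age", "omega", "sigma_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.d_max_low >= self.d_max_high:
            raise ValueError("d_max_low must be < d_max_high")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive when set")

    # -- derived quantities -------------------------------------------------

    @property
    def k_m(self) -> float:
        """Mean aggressiveness exp(mu_k + sigma_k^2/2) (month^-1)."""
        return derived_k_mean(self.mu_k, self.sigma_k)

    @property
    def alpha_eff(self) -> float:
        """Effective treatment-effectiveness exponent (default derived)."""
        if self.alpha is not None:
            return self.alpha
        return derived_alpha(self.Q, self.omega, self.k_m)

    def half_detection_diameter(self, modality: str) -> float:
        """Diameter (mm) at which the given modality detects with prob 1/2."""
        try:
            return {
                "before_study": self.b_b2,
                "mammography": self.b_m2,
                "physical": self.b_p2,
                "self": self.b_s2,
            }[modality]
        except KeyError:
            raise ValueError(
                f"unknown modality {modality!r}; expected one of {MODALITIES}"
            ) from None

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def with_(self, **overrides: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


DEFAULT_PARAMS = ModelParams()
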