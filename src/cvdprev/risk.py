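"""Annual first-event probabilities for an index cohort.

Ten-year risks of a first coronary event (MI) and a first stroke are
computed from Framingham-style Weibull accelerated-failure-time equations

    p(t) = 1 - exp(-exp((ln t - mu) / sigma)),

with the location ``mu`` a function of age, sex, systolic blood pressure,
total/HDL cholesterol ratio, smoking, diabetes and left-ventricular
hypertrophy, and the scale ``sigma`` log-linear in the same linear
predictor.  Coefficients are shipped as versioned CSV files under
``cvdprev/data`` (the coronary set is the published Anderson-1991 total-CHD
equation; the stroke set is a clearly-labelled synthetic calibration of the
same functional form).

Ten-year risks are converted to the model's annual cycle under a
constant-hazard assumption.  Annual probabilities may also be specified
directly, bypassing the equations entirely.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from importlib import resources

from .domain import RiskFactorProfile, RiskLevel

__all__ = [
    "AnnualEventRisks",
    "ten_year_event_risk",
    "annualize",
    "annual_risks_for_level",
    "VALID_AGE_RANGE",
]

logger = logging.getLogger(__name__)

#: Published validity range of the risk equations; ages outside are clamped.
VALID_AGE_RANGE = (30, 74)

_COEFF_FILES = {
    "mi": "coronary_aft_anderson1991.csv",
    "stroke": "stroke_aft_synthetic.csv",
}

_coeff_cache: dict[str, dict[str, float]] = {}


def _coefficients(endpoint: str) -> dict[str, float]:
    if endpoint not in _COEFF_FILES:
        raise ValueError(f"unsupported endpoint: {endpoint!r} (use 'mi' or 'stroke')")
    if endpoint not in _coeff_cache:
        ref = resources.files("cvdprev.data") / _COEFF_FILES[endpoint]
        with ref.open() as fh:
            rows = [r for r in csv.DictReader(
                (line for line in fh if not line.startswith("#"))
            )]
        _coeff_cache[endpoint] = {r["parameter"]: float(r["value"]) for r in rows}
    return _coeff_cache[endpoint]


@dataclass
class AnnualEventRisks:
    """Annual probabilities of a first MI and a first stroke for one cohort."""

    p_mi_annual: float
    p_stroke_annual: float
    source: str  # "framingham_derived" | "directly_specified"


def ten_year_event_risk(
    profile: RiskFactorProfile, endpoint: str, horizon_years: float = 10.0
) -> float:
    """Risk of a first event of ``endpoint`` ("mi" or "stroke") over
    ``horizon_years`` for the given profile.

    Ages outside the equations' validity range (30-74) are clamped with a
    logged warning.  Strictly increasing in age (within range), systolic BP,
    total cholesterol, smoking and diabetes.
    """
    c = _coefficients(endpoint)
    age = float(profile.age_years)
    lo, hi = VALID_AGE_RANGE
    if age < lo or age > hi:
        logger.warning(
            "age %s outside risk-equation validity range %s; clamping", age, VALID_AGE_RANGE
        )
        age = min(max(age, lo), hi)

    ratio = profile.total_cholesterol_mmol_per_L / profile.hdl_cholesterol_mmol_per_L
    a = (
        c["const_a"]
        + c["ln_sbp"] * math.log(profile.systolic_bp_mmHg)
        + c["smoker"] * float(profile.smoker)
        + c["ln_tc_hdl"] * math.log(ratio)
        + c["lvh"] * float(profile.lvh)
    )
    if profile.sex == "male":
        m = a + c["male_ln_age"] * math.log(age) + c["male_diabetes"] * float(profile.diabetic)
    else:
        m = (
            a
            + c["female_const"]
            + c["female_ln_age74_sq"] * math.log(age / 74.0) ** 2
            + c["female_diabetes"] * float(profile.diabetic)
        )
    mu = c["mu_offset"] + m
    sigma = math.exp(c["sigma_const"] + c["sigma_m"] * m)
    u = (math.log(horizon_years) - mu) / sigma
    p = 1.0 - math.exp(-math.exp(u))
    if not math.isfinite(p) or not (0.0 < p < 1.0):
        raise ArithmeticError(
            f"non-finite or degenerate risk {p!r} for endpoint {endpoint}: "
            "coefficient misconfiguration?"
        )
    return p


def annualize(p_horizon: float, horizon_years: float) -> float:
    """Convert a cumulative probability over ``horizon_years`` to an annual
    probability under a constant hazard: 1 - (1 - p)^(1/T)."""
    if not (0.0 <= p_horizon <= 1.0):
        raise ValueError(f"p_horizon must lie in [0, 1], got {p_horizon}")
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    return 1.0 - (1.0 - p_horizon) ** (1.0 / horizon_years)


def annual_risks_for_level(
    level: RiskLevel,
    profile: RiskFactorProfile | None = None,
    *,
    p_mi_annual: float | None = None,
    p_stroke_annual: float | None = None,
) -> AnnualEventRisks:
    """Annual first-event risks for one risk level.

    Either a profile is given (risks derived from the risk equations and
    annualized) or both annual probabilities are specified directly.  The
    ``level`` argument documents which band the cohort represents; with the
    packaged index profiles every risk component increases strictly across
    low < moderate < high < very_high.
    """
    del level  # descriptive only; risks come from the profile or overrides
    if p_mi_annual is not None or p_stroke_annual is not None:
        if p_mi_annual is None or p_stroke_annual is None:
            raise ValueError("both p_mi_annual and p_stroke_annual must be specified")
        risks = AnnualEventRisks(p_mi_annual, p_stroke_annual, "directly_specified")
    elif profile is not None:
        p_mi = annualize(ten_year_event_risk(profile, "mi"), 10.0)
        p_stroke = annualize(ten_year_event_risk(profile, "stroke"), 10.0)
        risks = AnnualEventRisks(p_mi, p_stroke, "framingham_derived")
    else:
        raise ValueError("either a profile or direct annual probabilities are required")
    for name, p in (("p_mi_annual", risks.p_mi_annual),
                    ("p_stroke_annual", risks.p_stroke_annual)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if risks.p_mi_annual + risks.p_stroke_annual > 1.0:
        raise ValueError(
            "annual MI and stroke probabilities sum above 1; competing first "
            "events cannot exceed the cycle"
        )
    return risks
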