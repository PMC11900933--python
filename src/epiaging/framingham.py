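"""2008 Framingham general-CVD risk and vascular (heart) age.

The 10-year risk of a first general cardiovascular event is computed
from the sex-specific Cox risk functions (lipid-based variant; see
:mod:`epiaging.framingham_constants`).  Vascular age is the age at
which a same-sex person with every other risk factor at the normal
reference level would carry the same predicted risk; it is obtained by
inverting the risk function over age with a bracketed root finder,
because risk is strictly increasing in age when all other factors are
held fixed.  Vascular ageing is vascular age minus chronological age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .framingham_constants import (
    COEFFICIENTS,
    REFERENCE_NORMALS,
    VALID_AGE_RANGE,
)

__all__ = [
    "RiskFactorProfile",
    "ReferenceProfile",
    "FRSResult",
    "general_cvd_risk",
    "vascular_age",
    "vascular_ageing",
    "assess_profile",
]

#: Search bracket (years) for the vascular-age inversion.
AGE_BRACKET = (15.0, 120.0)


@dataclass(frozen=True)
class RiskFactorProfile:
    """The seven Framingham general-CVD inputs for one subject.

    Units: age years, SBP mmHg, cholesterol mg/dL.  The risk function's
    nominal validity range is ages 30-74; outside 20-100 a warning is
    emitted but the value is still computed.
    """

    age: float
    sex: str  # "female" | "male"
    sbp: float
    on_htn_treatment: bool
    smoker: bool
    diabetic: bool
    total_chol: float
    hdl_chol: float

    def __post_init__(self) -> None:
        sex = self.sex.lower()
        if sex in ("f", "female"):
            object.__setattr__(self, "sex", "female")
        elif sex in ("m", "male"):
            object.__setattr__(self, "sex", "male")
        else:
            raise ValueError(f"sex must be female/male (or F/M), got {self.sex!r}")
        if self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        for name in ("sbp", "total_chol", "hdl_chol"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-sex 'all factors normal' values used to define vascular age:
    untreated SBP, non-smoker, non-diabetic, reference lipids."""

    sbp: float
    total_chol: float
    hdl_chol: float

    @classmethod
    def default(cls, sex: str) -> "ReferenceProfile":
        key = "female" if sex.lower() in ("f", "female") else "male"
        return cls(**REFERENCE_NORMALS[key])

    def at_age(self, age: float, sex: str) -> RiskFactorProfile:
        return RiskFactorProfile(
            age=age, sex=sex, sbp=self.sbp, on_htn_treatment=False,
            smoker=False, diabetic=False,
            total_chol=self.total_chol, hdl_chol=self.hdl_chol)


@dataclass(frozen=True)
class FRSResult:
    """Risk as a probability, vascular age in years, and their
    difference from chronological age; ``flags`` records saturation of
    the age inversion ('saturated'/'floored') and validity-range
    notes."""

    risk_10yr: float
    vascular_age: float
    vascular_ageing: float
    flags: tuple[str, ...] = field(default=())


def _linear_predictor(profile: RiskFactorProfile, age: float | None = None) -> float:
    c = COEFFICIENTS[profile.sex]
    a = profile.age if age is None else age
    sbp_beta = c["ln_sbp_treated"] if profile.on_htn_treatment else c["ln_sbp_untreated"]
    return (c["ln_age"] * math.log(a)
            + c["ln_total_chol"] * math.log(profile.total_chol)
            + c["ln_hdl_chol"] * math.log(profile.hdl_chol)
            + sbp_beta * math.log(profile.sbp)
            + c["smoker"] * profile.smoker
            + c["diabetic"] * profile.diabetic)


def general_cvd_risk(profile: RiskFactorProfile, *, _age: float | None = None) -> float:
    """Sex-specific 10-year general-CVD risk as a probability in [0, 1].

    ``1 - S0(10) ** exp(lp - mean_lp)`` with the Cox linear predictor
    ``lp`` on log-transformed continuous factors.  Strictly increasing
    in age, SBP, total cholesterol, smoking and diabetes, and strictly
    decreasing in HDL.
    """
    age = profile.age if _age is None else _age
    if _age is None and not 20.0 <= profile.age <= 100.0:
        warnings.warn(
            f"age {profile.age} y is outside 20-100; the Framingham risk "
            "function is extrapolated", stacklevel=2)
    c = COEFFICIENTS[profile.sex]
    lp = _linear_predictor(profile, age)
    return 1.0 - c["baseline_survival_10yr"] ** math.exp(lp - c["mean_lp"])


def _reference_risk(age: float, sex: str, ref: ReferenceProfile) -> float:
    return general_cvd_risk(ref.at_age(AGE_BRACKET[0], sex), _age=age)


def vascular_age(
    profile: RiskFactorProfile,
    ref: ReferenceProfile | None = None,
) -> tuple[float, str | None]:
    """Invert the reference risk curve: the age at which a same-sex
    subject with all other factors at reference level matches
    ``profile``'s predicted risk.

    Returns ``(age_years, flag)``.  If the target risk lies above the
    reference risk at 120 y the result saturates at 120 ('saturated');
    below the reference risk at 15 y it floors at 15 ('floored');
    otherwise the flag is ``None`` and the root satisfies
    ``|risk(a) - target| / target <= 1e-10``.
    """
    if ref is None:
        ref = ReferenceProfile.default(profile.sex)
    target = general_cvd_risk(profile)
    lo, hi = AGE_BRACKET
    risk_lo = _reference_risk(lo, profile.sex, ref)
    risk_hi = _reference_risk(hi, profile.sex, ref)
    if risk_lo >= risk_hi:
        raise RuntimeError(
            "reference risk is not increasing in age: corrupted Framingham "
            "constants")
    if target >= risk_hi:
        return hi, "saturated"
    if target <= risk_lo:
        return lo, "floored"
    # Root of a strictly monotone, smooth function; brentq converges in
    # a handful of iterations at this tolerance.
    age = brentq(
        lambda a: _reference_risk(a, profile.sex, ref) - target,
        lo, hi, xtol=1e-9, rtol=8.9e-16)
    return float(age), None


def vascular_ageing(va: float, chronological_age: float) -> float:
    """Signed difference vascular age - chronological age, in years."""
    if not (math.isfinite(va) and math.isfinite(chronological_age)):
        raise ValueError("ages must be finite")
    return va - chronological_age


def assess_profile(
    profile: RiskFactorProfile,
    ref: ReferenceProfile | None = None,
) -> FRSResult:
    """Risk, vascular age and vascular ageing for one subject."""
    flags: list[str] = []
    lo, hi = VALID_AGE_RANGE
    if not lo <= profile.age <= hi:
        flags.append("age_outside_validity")
    risk = general_cvd_risk(profile)
    va, flag = vascular_age(profile, ref)
    if flag:
        flags.append(flag)
    return FRSResult(
        risk_10yr=risk,
        vascular_age=va,
        vascular_ageing=vascular_ageing(va, profile.age),
        flags=tuple(flags))
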