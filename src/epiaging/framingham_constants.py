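"""Coefficients of the 2008 Framingham general-CVD risk functions.

Provenance: transcribed from D'Agostino RB Sr, Vasan RS, Pencina MJ,
et al. "General cardiovascular risk profile for use in primary care:
the Framingham Heart Study." Circulation 2008;117(6):743-753, Table 2
(sex-specific Cox models, lipid-based variant).  Version pinned:
transcription revision 1; any edit here must bump the revision and
re-validate against that paper's worked example (61-year-old female
smoker, TC 180 mg/dL, HDL 47 mg/dL, untreated SBP 124 mmHg, no
diabetes -> 10-year risk 10.48%).

The risk function is Cox-form:

    risk(10 y) = 1 - S0(10) ** exp(sum_i beta_i * x_i - M)

where x_i are ln(age), ln(total cholesterol), ln(HDL), ln(SBP)
(separate coefficients for treated/untreated blood pressure), and 0/1
indicators for smoking and diabetes; M is the sum of beta_i * mean(x_i)
in the derivation cohort and S0(10) the baseline 10-year survival.
"""

from __future__ import annotations

import hashlib
import json

TRANSCRIPTION_REVISION = 1

#: Sex-specific Cox coefficients (betas multiply ln-transformed
#: continuous factors and binary indicators), the derivation-cohort
#: linear-predictor mean, and baseline 10-year survival.
COEFFICIENTS: dict[str, dict[str, float]] = {
    "female": {
        "ln_age": 2.32888,
        "ln_total_chol": 1.20904,
        "ln_hdl_chol": -0.70833,
        "ln_sbp_untreated": 2.76157,
        "ln_sbp_treated": 2.82263,
        "smoker": 0.52873,
        "diabetic": 0.69154,
        "mean_lp": 26.1931,
        "baseline_survival_10yr": 0.95012,
    },
    "male": {
        "ln_age": 3.06117,
        "ln_total_chol": 1.12370,
        "ln_hdl_chol": -0.93263,
        "ln_sbp_untreated": 1.93303,
        "ln_sbp_treated": 1.99881,
        "smoker": 0.65451,
        "diabetic": 0.57367,
        "mean_lp": 23.9802,
        "baseline_survival_10yr": 0.88936,
    },
}

#: "All risk factors at normal levels" reference used for vascular
#: (heart) age: the normal-level values used for heart age in the 2008
#: publication -- non-smoker, non-diabetic, untreated SBP 125 mmHg,
#: total cholesterol 180 mg/dL, HDL 45 mg/dL, identical for both sexes.
#: Overridable via configuration.
REFERENCE_NORMALS: dict[str, dict[str, float]] = {
    "female": {"sbp": 125.0, "total_chol": 180.0, "hdl_chol": 45.0},
    "male": {"sbp": 125.0, "total_chol": 180.0, "hdl_chol": 45.0},
}

#: Nominal age validity range of the derivation cohort, years.
VALID_AGE_RANGE = (30.0, 74.0)


def constants_checksum() -> str:
    """SHA-256 over the canonical JSON form of the coefficient tables.

    Logged by the pipeline so reports are traceable to an exact
    transcription of the risk function.
    """
    payload = json.dumps(
        {"revision": TRANSCRIPTION_REVISION, "coefficients": COEFFICIENTS,
         "reference": REFERENCE_NORMALS},
        sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
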