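"""End-to-end cohort analysis.

Given a cohort table, compute per-subject epigenetic age and
acceleration (clock stage), 10-year general-CVD risk, vascular age and
vascular ageing (risk stage), and HOMA-IR (metabolic stage), then emit
four reports:

1. a group-summary table over every available variable (rank-sum /
   chi-squared, median [q25; q75] formatting);
2. a within-group Spearman sweep of epigenetic age and age
   acceleration against every numeric covariate;
3. within-group correlations of epigenetic age with chronological age
   and with vascular age;
4. two-group contrasts of epigenetic age, vascular age, age
   acceleration and vascular ageing.

Stages whose required columns are absent are skipped with an explicit
log entry; the pipeline is a pure function of its inputs.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biochem import glucose_mgdl_to_mmol, homa_ir
from .clock import CLOCK_SITES, DEFAULT_CLOCK, ClockModel, MethylationProfile, \
    predict_epigenetic_age
from .cohort_stats import build_table1, format_p, rank_sum_test, \
    spearman_correlation
from .framingham import ReferenceProfile, RiskFactorProfile, assess_profile
from .framingham_constants import constants_checksum
from .io import read_cohort

__all__ = ["run_pipeline", "FRS_COLUMNS"]

logger = logging.getLogger("epiaging")

FRS_COLUMNS = ("age_years", "sex", "sbp_mmhg", "htn_treated", "smoker",
               "diabetes", "tc_mgdl", "hdl_mgdl")

_CONTRAST_VARS = ("epigenetic_age", "vascular_age", "age_acceleration",
                  "vascular_ageing")


def _clock_stage(df: pd.DataFrame, model: ClockModel,
                 strict_percent: bool) -> None:
    epi = np.full(len(df), np.nan)
    for i, (_, row) in enumerate(df.iterrows()):
        vals = [row[s] for s in CLOCK_SITES]
        if any(pd.isna(v) for v in vals):
            continue
        profile = MethylationProfile(str(row["sample_id"]), *vals)
        epi[i] = predict_epigenetic_age(profile, model,
                                        strict_percent=strict_percent)
    df["epigenetic_age"] = epi
    if "age_years" in df.columns:
        df["age_acceleration"] = df["epigenetic_age"] - df["age_years"]


def _frs_stage(df: pd.DataFrame, ref_by_sex: dict[str, ReferenceProfile] | None) -> None:
    risk = np.full(len(df), np.nan)
    va = np.full(len(df), np.nan)
    flags: list[str] = []
    for i, (_, row) in enumerate(df.iterrows()):
        vals = [row[c] for c in FRS_COLUMNS]
        if any(pd.isna(v) for v in vals):
            flags.append("")
            continue
        profile = RiskFactorProfile(
            age=float(row["age_years"]), sex=str(row["sex"]),
            sbp=float(row["sbp_mmhg"]),
            on_htn_treatment=bool(row["htn_treated"]),
            smoker=bool(row["smoker"]), diabetic=bool(row["diabetes"]),
            total_chol=float(row["tc_mgdl"]), hdl_chol=float(row["hdl_mgdl"]))
        ref = ref_by_sex.get(profile.sex) if ref_by_sex else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-row range warnings -> flags
            res = assess_profile(profile, ref)
        risk[i] = res.risk_10yr
        va[i] = res.vascular_age
        flags.append(";".join(res.flags))
    df["frs_risk_pct"] = risk * 100.0
    df["vascular_age"] = va
    df["vascular_ageing"] = df["vascular_age"] - df["age_years"]
    df["frs_flags"] = flags


def _metabolic_stage(df: pd.DataFrame) -> None:
    glu = df["glucose_mgdl"].map(
        lambda g: glucose_mgdl_to_mmol(g) if pd.notna(g) else np.nan)
    df["homa_ir"] = [
        homa_ir(i, g) if pd.notna(i) and pd.notna(g) else np.nan
        for i, g in zip(df["insulin_uiu_ml"], glu)]


def _correlation_sweep(df: pd.DataFrame, group_col: str,
                       responses: list[str]) -> pd.DataFrame:
    """Within-group Spearman rho of each response vs every numeric
    covariate (all coefficients reported, significant or not)."""
    numeric = [c for c in df.columns
               if pd.api.types.is_numeric_dtype(df[c])
               and c not in responses and c != group_col]
    rows = []
    for group, sub in df.groupby(group_col, sort=False):
        for resp in responses:
            if resp not in sub.columns:
                continue
            for cov in numeric:
                pair = sub[[resp, cov]].dropna()
                if len(pair) < 3 or pair[cov].nunique() < 2 \
                        or pair[resp].nunique() < 2:
                    continue
                res = spearman_correlation(pair[resp], pair[cov])
                rows.append({"group": group, "response": resp,
                             "covariate": cov, "rho": res.rho,
                             "p_value": res.p_value,
                             "p_display": format_p(res.p_value),
                             "n": res.n})
    return pd.DataFrame(rows)


def _age_correlations(df: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Within-group epigenetic age vs chronological and vascular age."""
    rows = []
    pairs = [("epigenetic_age", "age_years"), ("epigenetic_age", "vascular_age")]
    for group, sub in df.groupby(group_col, sort=False):
        for a, b in pairs:
            if a not in sub.columns or b not in sub.columns:
                continue
            pair = sub[[a, b]].dropna()
            if len(pair) < 3:
                continue
            res = spearman_correlation(pair[a], pair[b])
            rows.append({"group": group, "x": a, "y": b, "rho": res.rho,
                         "p_value": res.p_value,
                         "p_display": format_p(res.p_value), "n": res.n})
    return pd.DataFrame(rows)


def _group_contrasts(df: pd.DataFrame, group_col: str) -> pd.DataFrame:
    groups = [g for g in df[group_col].unique() if pd.notna(g)]
    ga, gb = sorted(groups, key=str)
    rows = []
    for var in _CONTRAST_VARS:
        if var not in df.columns:
            continue
        a = df.loc[df[group_col] == ga, var].dropna()
        b = df.loc[df[group_col] == gb, var].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        res = rank_sum_test(a, b, name=var)
        rows.append({
            "variable": var,
            f"group_{ga}": f"{res.median_a:.1f} [{res.q25_a:.1f}; {res.q75_a:.1f}]",
            f"group_{gb}": f"{res.median_b:.1f} [{res.q25_b:.1f}; {res.q75_b:.1f}]",
            "statistic": res.statistic, "p_value": res.p_value,
            "p_display": res.p_display})
    return pd.DataFrame(rows)


def run_pipeline(
    cohort: pd.DataFrame | str | Path,
    group_col: str = "group",
    clock_model: ClockModel = DEFAULT_CLOCK,
    reference: dict[str, ReferenceProfile] | None = None,
    strict_percent: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run every stage the cohort's columns support.

    Returns a dict with keys ``per_subject``, ``table1``,
    ``correlation_sweep``, ``age_correlations`` and
    ``group_contrasts`` (report keys only for stages that ran).
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = read_cohort(cohort)
    df = cohort.copy()
    logger.info("epiaging %s; Framingham constants sha256=%s; n=%d",
                __version__, constants_checksum(), len(df))

    if all(s in df.columns for s in CLOCK_SITES):
        _clock_stage(df, clock_model, strict_percent)
        logger.info("clock stage: done")
    else:
        missing = [s for s in CLOCK_SITES if s not in df.columns]
        logger.info("clock stage: skipped (missing columns %s)", missing)

    if all(c in df.columns for c in FRS_COLUMNS):
        _frs_stage(df, reference)
        logger.info("risk stage: done")
    else:
        missing = [c for c in FRS_COLUMNS if c not in df.columns]
        logger.info("risk stage: skipped (missing columns %s)", missing)

    if {"glucose_mgdl", "insulin_uiu_ml"} <= set(df.columns):
        _metabolic_stage(df)
        logger.info("metabolic stage: done")
    else:
        logger.info("metabolic stage: skipped (missing glucose/insulin)")

    out: dict[str, pd.DataFrame] = {"per_subject": df}
    two_groups = (group_col in df.columns
                  and df[group_col].dropna().nunique() == 2)
    if two_groups:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-variable skip warnings logged
            out["table1"] = build_table1(
                df.drop(columns=["frs_flags"], errors="ignore"),
                group_col=group_col)
        responses = [r for r in ("epigenetic_age", "age_acceleration")
                     if r in df.columns]
        if responses:
            out["correlation_sweep"] = _correlation_sweep(df, group_col,
                                                          responses)
        corr = _age_correlations(df, group_col)
        if not corr.empty:
            out["age_correlations"] = corr
        contrasts = _group_contrasts(df, group_col)
        if not contrasts.empty:
            out["group_contrasts"] = contrasts
        logger.info("reports: %s", sorted(set(out) - {"per_subject"}))
    else:
        logger.info("group reports: skipped (need exactly 2 groups in %r)",
                    group_col)
    return out
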