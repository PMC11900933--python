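"""Cohort table input/output.

The canonical cohort file is a delimited text table (comma or tab,
sniffed), one subject per row, UTF-8, decimal point.  Canonical column
names and units:

``sample_id``; ``group`` (two labels, default EOB/PWS); ``sex`` (F/M);
``age_years``; the five clock CpG columns ``ELOVL2_C7, C1orf132_C1,
TRIM59_C7, KLF14_C1, FHL2_C2`` (percent methylation, aliases such as
MIR29B2C accepted); ``sbp_mmhg``, ``dbp_mmhg``, ``hr_bpm``;
``htn_treated``, ``smoker``, ``diabetes``, ``rhgh_treated`` (0/1);
``tc_mgdl``, ``hdl_mgdl``, ``ldl_mgdl``, ``tg_mgdl``,
``glucose_mgdl``, ``insulin_uiu_ml``, ``hscrp_mgdl``; ``bmi_kgm2``,
``wc_cm``, ``ffm_kg``, ``ffm_pct``, ``fm_kg``, ``fm_pct``,
``hba1c_pct``; ``rhgh_years``, ``igf1_ngml``.

Unknown columns pass through untouched; missing values stay explicit
(empty field -> NaN).  Errors cite the offending file line.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .clock import CLOCK_SITES, canonical_site_name

__all__ = [
    "NUMERIC_COLUMNS",
    "BOOL_COLUMNS",
    "SubjectRecord",
    "read_cohort",
    "write_cohort",
    "to_records",
]

NUMERIC_COLUMNS: tuple[str, ...] = (
    "age_years", *CLOCK_SITES,
    "sbp_mmhg", "dbp_mmhg", "hr_bpm",
    "tc_mgdl", "hdl_mgdl", "ldl_mgdl", "tg_mgdl",
    "glucose_mgdl", "insulin_uiu_ml", "hscrp_mgdl",
    "bmi_kgm2", "wc_cm", "ffm_kg", "ffm_pct", "fm_kg", "fm_pct",
    "hba1c_pct", "rhgh_years", "igf1_ngml",
)

BOOL_COLUMNS: tuple[str, ...] = ("htn_treated", "smoker", "diabetes",
                                 "rhgh_treated")

_SEX_CODES = {"f": "F", "female": "F", "m": "M", "male": "M"}
_BOOL_CODES = {"0": 0, "1": 1, "false": 0, "true": 1, "no": 0, "yes": 1}


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort row as a typed record; NaN/None mark missing values."""

    sample_id: str
    group: str | None = None
    sex: str | None = None
    age_years: float | None = None
    elovl2_c7: float | None = None
    c1orf132_c1: float | None = None
    trim59_c7: float | None = None
    klf14_c1: float | None = None
    fhl2_c2: float | None = None
    sbp_mmhg: float | None = None
    htn_treated: int | None = None
    smoker: int | None = None
    diabetes: int | None = None
    tc_mgdl: float | None = None
    hdl_mgdl: float | None = None
    ldl_mgdl: float | None = None
    tg_mgdl: float | None = None
    glucose_mgdl: float | None = None
    insulin_uiu_ml: float | None = None
    hscrp_mgdl: float | None = None
    extras: tuple = ()


def _canonicalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Map methylation aliases and case variants onto canonical names."""
    rename: dict[str, str] = {}
    for col in df.columns:
        try:
            canon = canonical_site_name(col)
        except KeyError:
            low = col.strip().lower()
            for known in ("sample_id", "group", "sex", *NUMERIC_COLUMNS,
                          *BOOL_COLUMNS):
                if low == known.lower() and col != known:
                    rename[col] = known
                    break
            continue
        if canon != col:
            rename[col] = canon
    out = df.rename(columns=rename)
    dup = out.columns[out.columns.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate columns after alias resolution: {list(dup)}")
    return out


def _line_of(df: pd.DataFrame, mask: pd.Series) -> int:
    # +2: header line plus 1-based numbering
    return int(df.index[mask][0]) + 2


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table; returns a typed DataFrame.

    Rejects duplicate sample ids, unparseable numerics and unknown
    sex/group/boolean codes, naming the file line in the message.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    if "sample_id" not in [c.strip().lower() for c in df.columns]:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    df.columns = [c.strip() for c in df.columns]
    df = _canonicalise_columns(df)

    dup = df["sample_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate sample_id {df['sample_id'][dup].iloc[0]!r} "
            f"at line {_line_of(df, dup)}")

    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            raise ValueError(
                f"{path}: unparseable value {raw[bad].iloc[0]!r} in column "
                f"{col!r} at line {_line_of(df, bad)}")
        df[col] = parsed

    for col in BOOL_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col]
        norm = raw.str.strip().str.lower().map(_BOOL_CODES)
        bad = norm.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            raise ValueError(
                f"{path}: unknown boolean code {raw[bad].iloc[0]!r} in column "
                f"{col!r} at line {_line_of(df, bad)}")
        df[col] = norm.astype("Int64")

    if "sex" in df.columns:
        raw = df["sex"]
        norm = raw.str.strip().str.lower().map(_SEX_CODES)
        bad = norm.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            raise ValueError(
                f"{path}: unknown sex code {raw[bad].iloc[0]!r} "
                f"at line {_line_of(df, bad)}")
        df["sex"] = norm
    if "group" in df.columns:
        df["group"] = df["group"].str.strip()
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; tab-separated for .tsv, comma otherwise."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    """Typed row view of a cohort DataFrame (known columns only)."""
    known = {f.name for f in dataclasses.fields(SubjectRecord)} - {"extras"}
    col_map = {"elovl2_c7": "ELOVL2_C7", "c1orf132_c1": "C1orf132_C1",
               "trim59_c7": "TRIM59_C7", "klf14_c1": "KLF14_C1",
               "fhl2_c2": "FHL2_C2"}
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in known:
            col = col_map.get(name, name)
            if col in df.columns:
                val = row[col]
                kwargs[name] = None if pd.isna(val) else val
        extras = tuple((c, row[c]) for c in df.columns
                       if c not in set(col_map.values()) | known)
        records.append(SubjectRecord(extras=extras, **kwargs))
    return records
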