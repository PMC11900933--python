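"""Five-CpG DNA-methylation age clock.

A linear predictor of chronological age from percent methylation
(pyrosequencing scale, 0-100) at single CpG sites in five genes:
ELOVL2, C1orf132/MIR29B2C, TRIM59, KLF14 and FHL2.  The default
coefficients are the published blood-clock values; the model is never
re-estimated here.  Age acceleration is the signed difference between
predicted (epigenetic) age and chronological age: negative values mean
an epigenetically younger profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Mapping

__all__ = [
    "CLOCK_SITES",
    "SITE_ALIASES",
    "MethylationProfile",
    "ClockModel",
    "AgeResult",
    "predict_epigenetic_age",
    "age_acceleration",
    "predict_cohort",
]

#: Canonical site column names, in model order. The suffix is the CpG
#: position within the pyrosequencing amplicon (C7 = 7th CpG, etc.).
CLOCK_SITES = ("ELOVL2_C7", "C1orf132_C1", "TRIM59_C7", "KLF14_C1", "FHL2_C2")

#: Accepted aliases -> canonical name.  C1orf132 is also annotated as
#: MIR29B2C (host gene of miR-29b2/c), so both spellings are accepted.
SITE_ALIASES: Mapping[str, str] = {
    "ELOVL2": "ELOVL2_C7",
    "C1ORF132": "C1orf132_C1",
    "C1ORF132_C1": "C1orf132_C1",
    "MIR29B2C": "C1orf132_C1",
    "MIR29B2C_C1": "C1orf132_C1",
    "TRIM59": "TRIM59_C7",
    "KLF14": "KLF14_C1",
    "FHL2": "FHL2_C2",
}


def canonical_site_name(name: str) -> str:
    """Resolve a site column name (case-insensitive, aliases allowed).

    Raises ``KeyError`` for names that are not clock sites.
    """
    upper = name.strip().upper()
    for canon in CLOCK_SITES:
        if upper == canon.upper():
            return canon
    if upper in SITE_ALIASES:
        return SITE_ALIASES[upper]
    raise KeyError(f"unknown clock CpG site: {name!r}")


@dataclass(frozen=True)
class MethylationProfile:
    """Percent methylation at the five clock CpG sites for one sample.

    Values are percentages in [0, 100]; a missing measurement is ``None``,
    never 0.  Attribute order matches the model's coefficient order.
    """

    sample_id: str
    elovl2_c7: float | None = None
    c1orf132_c1: float | None = None
    trim59_c7: float | None = None
    klf14_c1: float | None = None
    fhl2_c2: float | None = None

    def values(self) -> tuple[float | None, ...]:
        return (self.elovl2_c7, self.c1orf132_c1, self.trim59_c7,
                self.klf14_c1, self.fhl2_c2)

    def validate(self, strict_percent: bool = False) -> None:
        """Check all five sites are present, finite and on the percent scale.

        A profile whose five values all lie in [0, 1] with at least one
        nonzero looks like fraction-scale (0-1) data rather than
        percent; with ``strict_percent`` such a profile is rejected,
        otherwise it triggers a warning.  A single low site is not
        flagged: sub-1% methylation at one CpG is a legitimate
        pyrosequencing reading.
        """
        for site, value in zip(CLOCK_SITES, self.values()):
            if value is None:
                raise ValueError(
                    f"sample {self.sample_id!r}: missing methylation at {site}")
            if not math.isfinite(value):
                raise ValueError(
                    f"sample {self.sample_id!r}: non-finite methylation at {site}")
            if not 0.0 <= value <= 100.0:
                raise ValueError(
                    f"sample {self.sample_id!r}: methylation at {site} is "
                    f"{value}, outside the percent range [0, 100]")
        values = self.values()
        if all(v <= 1.0 for v in values) and any(v > 0.0 for v in values):
            msg = (f"sample {self.sample_id!r}: all five methylation values "
                   "lie in [0, 1] and may be on the fraction scale rather "
                   "than percent")
            if strict_percent:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)


@dataclass(frozen=True)
class ClockModel:
    """Intercept (years) and per-site coefficients (years per percentage
    point) of the linear clock.  Defaults are the published values; the
    C1orf132 term is the sole negative one (methylation at that site
    decreases with age)."""

    intercept: float = 3.26847784751817
    coef_elovl2: float = 0.465445549010653
    coef_c1orf132: float = -0.355450171437202
    coef_trim59: float = 0.306488541137007
    coef_klf14: float = 0.832684435238792
    coef_fhl2: float = 0.237081243617191

    def __post_init__(self) -> None:
        for f in fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValueError(f"non-finite clock parameter {f.name}")

    @property
    def coefficients(self) -> tuple[float, ...]:
        """Site coefficients in canonical site order."""
        return (self.coef_elovl2, self.coef_c1orf132, self.coef_trim59,
                self.coef_klf14, self.coef_fhl2)


DEFAULT_CLOCK = ClockModel()


@dataclass(frozen=True)
class AgeResult:
    """Per-sample clock output; acceleration present iff chronological
    age was supplied, and then equals epigenetic - chronological exactly."""

    sample_id: str
    epigenetic_age: float
    chronological_age: float | None = None
    age_acceleration: float | None = None


def predict_epigenetic_age(
    profile: MethylationProfile,
    model: ClockModel = DEFAULT_CLOCK,
    strict_percent: bool = False,
) -> float:
    """Epigenetic age in years: intercept + sum(coef_i * meth_i).

    Purely linear and deterministic; no clamping is applied, so extreme
    inputs can yield ages below zero (reported as-is, with a warning).
    """
    profile.validate(strict_percent=strict_percent)
    age = model.intercept
    for coef, meth in zip(model.coefficients, profile.values()):
        age += coef * meth
    if age < 0:
        warnings.warn(
            f"sample {profile.sample_id!r}: predicted epigenetic age "
            f"{age:.2f} y is negative; the linear clock has no floor",
            stacklevel=2)
    return age


def age_acceleration(epigenetic_age: float, chronological_age: float) -> float:
    """Signed difference epigenetic - chronological, in years."""
    if not (math.isfinite(epigenetic_age) and math.isfinite(chronological_age)):
        raise ValueError("ages must be finite")
    if chronological_age <= 0:
        raise ValueError(f"chronological age must be > 0, got {chronological_age}")
    return epigenetic_age - chronological_age


def predict_cohort(
    profiles: Iterable[MethylationProfile],
    ages: Mapping[str, float] | None = None,
    model: ClockModel = DEFAULT_CLOCK,
    strict_percent: bool = False,
) -> list[AgeResult]:
    """Run the clock over a cohort, preserving input order.

    ``ages`` maps sample_id to chronological age; samples without an
    entry get an AgeResult with acceleration absent.
    """
    ages = ages or {}
    profiles = list(profiles)
    seen: set[str] = set()
    for p in profiles:
        if p.sample_id in seen:
            raise ValueError(f"duplicate sample_id {p.sample_id!r}")
        seen.add(p.sample_id)
    results = []
    for p in profiles:
        epi = predict_epigenetic_age(p, model, strict_percent=strict_percent)
        chrono = ages.get(p.sample_id)
        accel = age_acceleration(epi, chrono) if chrono is not None else None
        results.append(AgeResult(p.sample_id, epi, chrono, accel))
    return results
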