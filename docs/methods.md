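# Methods

## The five-CpG clock

Epigenetic age is a fixed linear function of percent methylation at
five CpG sites (ELOVL2 C7, C1orf132/MIR29B2C C1, TRIM59 C7, KLF14 C1,
FHL2 C2). The coefficients are published constants for blood-derived
DNA measured by bisulphite pyrosequencing; the package never
re-estimates them. Consequences of linearity that the tests exploit:
the all-zero profile returns the intercept exactly, each site's
marginal effect is exactly its coefficient, and the prediction is
affine in any convex combination of profiles.

The model has no floor or ceiling. Extreme inputs (e.g. heavily
methylated C1orf132, the one site that loses methylation with age) can
produce negative ages; these are returned unclamped with a warning,
since silently truncating would bias cohort-level statistics.

Each site is treated as a single scalar percent value. Where an assay
reports multiple CpG positions per amplicon, the caller must reduce
them (typically the assay's designated position) before input.

## Vascular age by risk-function inversion

The 10-year general-CVD risk is the 2008 Framingham sex-specific Cox
form, risk = 1 − S₀(10)^exp(β·x − m), with log-transformed age, total
cholesterol, HDL and SBP (separate β for treated/untreated pressure)
plus smoking and diabetes indicators. The coefficient tables live in
`framingham_constants.py` with a provenance header and a SHA-256
checksum that the pipeline logs, so any edit to the transcription is
visible in downstream reports.

Vascular age inverts this function: holding every factor at the
per-sex "all normal" reference (untreated SBP 125 mmHg, TC 180 mg/dL,
HDL 45 mg/dL, non-smoker, non-diabetic — overridable via YAML), risk
is strictly increasing in age, so the age whose reference risk equals
the subject's risk is unique. The continuous Cox function is inverted
(Brent's method on [15, 120] years, age tolerance 1e−9 y, implying a
relative risk mismatch well under 1e−10) rather than the coarser
points-based chart, because vascular age is analysed downstream as a
continuous variable. Targets outside the bracket saturate at 120
("saturated") or floor at 15 ("floored") and are flagged rather than
extrapolated. Ages outside the derivation range 30–74 are computed but
flagged (`age_outside_validity`); outside 20–100 a warning marks overt
extrapolation.

## HOMA-IR and units

HOMA-IR = insulin [µIU/mL] × glucose [mmol/L] / 22.5. Glucose in
mg/dL is converted with the exact molar factor 1/18.016; the rounded
0.06 mmol/L per mg/dL occasionally quoted in assay documentation is
available behind `rounded_factor=True` for bit-compatibility with
older worksheets, but is not the default because the ~8% inflation it
introduces is a rounding artefact, not chemistry.

## Statistical layer

* Group summaries: median [25th; 75th percentile], type-7
  (linear-interpolation) quantiles — the numpy default, stated here
  because quartile conventions differ across software.
* Two-group continuous comparison: two-sided Mann–Whitney rank-sum.
  Exact null distribution when n₁+n₂ ≤ 20 and the pooled sample is
  tie-free; otherwise the normal approximation with mid-ranks,
  tie-variance correction and continuity correction. A Wilcoxon
  signed-rank test is provided separately and only for genuinely
  paired inputs: it is not defined for independent groups of unequal
  size, which is why the unpaired test is the group-comparison
  workhorse here.
* Categorical comparison: Pearson chi-squared without Yates correction
  (flag available); a warning fires when any expected count is < 5.
* Spearman correlation: Pearson correlation of mid-ranks. Two-sided p
  by full permutation enumeration for n ≤ 8 (exact even under ties),
  and by the t approximation on n−2 degrees of freedom for n > 8. The
  8! = 40 320 enumeration bound keeps the exact path under a
  millisecond; between 9 and 10 observations the t approximation is
  already adequate and enumeration cost grows factorially, so the
  switchover sits at 8.
* No multiple-testing correction by default — each comparison is
  reported at its raw level, matching common clinical-table practice;
  Benjamini–Hochberg adjustment is available via `fdr=True`.

## Synthetic cohort generator

The generator emulates a two-group adult obesity cohort (36 controls,
24 cases by default) for end-to-end testing and power/recovery
studies. Per subject:

* **Age** is truncated-normal on [18, 90] years, fitted to per-group
  quantile anchors (control 43.4 [30.6; 49.5], case 36.8 [26.6; 45.3]).
  A truncated normal, rather than a log-normal, is used for age because
  an adult inpatient cohort has a bounded, roughly symmetric age
  distribution; a heavy right tail would produce implausible 100+
  year-old subjects and compress the low end.
* **Methylation** at site i is baselineᵢ + slopeᵢ·t + ε, with
  t = age + offset·1[case] and ε ~ N(0, sd²) i.i.d. per site. The
  configured "shape" slopes and baselines (signs matching the clock:
  all sites gain methylation with age except C1orf132) are rescaled so
  the clock-weighted slope sum is exactly 1 and the clock-weighted
  baseline sum cancels the intercept; at zero noise the clock then
  returns t exactly, up to clamping of methylation into [0, 100]
  (a warning fires if more than 20% of values clamp).
* The **case-group clock offset** defaults to −12 years, the direction
  and approximate size of the epigenetic-age deficit the analysis is
  designed to detect. `recover_offset` estimates it as the difference
  in group median age acceleration.
* **Noise**: the default per-site sd of 4.0 percentage points
  aggregates technical and biological scatter around the age trend; it
  propagates to ≈ 4.4 y of epigenetic-age noise (the clock-coefficient
  norm is ≈ 1.09) and yields within-group Spearman correlations of
  ≈ 0.9 between epigenetic and chronological age, the strength typical
  of five-CpG clocks in adult cohorts.
* **Clinical covariates** (BMI, waist, body composition, SBP/DBP,
  heart rate, glucose, insulin, HbA1c, lipids, hsCRP) are log-normal,
  fitted per group to published median/IQR anchors by least squares in
  log space — sigma from the quartile ratio, location at the geometric
  mean of the three anchors. The balanced fit, rather than pinning the
  median exactly, matters when an anchor's median sits on an IQR edge
  (the case group's SBP, 130 [120; 130]): an exact-median fit would put
  half of all sample medians outside the IQR. Binary covariates
  (sex, smoking, diabetes, antihypertensive treatment) are Bernoulli
  per group; the case group additionally gets a hormone-replacement
  block (treatment indicator, treatment duration, IGF-1).

What the generator does **not** reproduce: between-covariate
correlation structure (insulin and BMI are drawn independently, so
composite quantities like HOMA-IR have the right location but not the
joint tail behaviour), longitudinal structure, assay batch effects, or
genotype subclasses within the case group. Passing tests on synthetic
cohorts therefore validate the analytic machinery — not any biological
claim about real cohorts.

Determinism: a cohort is a pure function of (config, seed); the test
suite asserts byte-identical regeneration.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to make their Monte-Carlo
tolerances comfortable: offset recovery at 500 subjects per group
(median-difference sampling error ≈ 0.3 y), type-I error at 10 000
null replicates of 25-vs-25 comparisons (binomial sd ≈ 0.2
percentage points around the nominal 5%), and inversion checks on 100
random risk profiles against a 0.001-year grid. All random tests are
seeded; hypothesis runs derandomised.

Degenerate inputs: empty groups, constant vectors (Spearman rho
undefined → NaN with a warning), zero marginals in contingency tables
and non-finite ages are rejected with messages naming the offending
quantity; cohort-file errors cite the file line.

## Known limitations

* The clock is assay-specific: coefficients assume pyrosequenced
  percent methylation at the exact CpG positions; array-derived beta
  values are not interchangeable inputs.
* The lipid-based Framingham variant is implemented; the office-based
  (BMI) variant is a possible extension.
* Vascular age saturates at 120 y by construction; cohort comparisons
  including saturated values understate extreme-risk differences.
* The group-comparison layer is purely rank-based; no covariate
  adjustment or regression modelling is provided.
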