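# epiaging

Tools for comparing **epigenetic age**, **chronological age** and
**vascular age** in two-group clinical cohorts — built for case–control
studies of syndromic versus essential obesity (e.g. Prader–Willi
syndrome vs non-syndromic obesity), but applicable to any cohort table
with the required columns.

The package bundles four pieces of machinery:

1. **A five-CpG DNA-methylation age clock.** Pyrosequencing yields the
   percentage of methylated cytosines at one CpG site in each of five
   genes — ELOVL2, C1orf132/MIR29B2C, TRIM59, KLF14 and FHL2. The
   epigenetic age is the published linear predictor

   Y = 3.26847784751817
     + 0.465445549010653 · meth(ELOVL2, C7)
     − 0.355450171437202 · meth(C1orf132, C1)
     + 0.306488541137007 · meth(TRIM59, C7)
     + 0.832684435238792 · meth(KLF14, C1)
     + 0.237081243617191 · meth(FHL2, C2)

   with methylation on the percent scale (0–100). **Age acceleration**
   is Y minus chronological age (negative = epigenetically younger).
   *Scale trap:* if your upstream software reports methylation as
   fractions in [0, 1], multiply by 100 first — the reader warns when a
   whole profile looks fraction-scaled, and rejects it with
   `--strict-percent`.

2. **2008 Framingham general-CVD risk and vascular age.** The
   sex-specific Cox risk functions (lipid-based variant) give the
   10-year risk from age, total and HDL cholesterol, SBP (treated or
   untreated), smoking and diabetes status. **Vascular age** is the age
   at which a same-sex person with all other factors at normal
   reference levels (untreated SBP 125 mmHg, TC 180 mg/dL, HDL
   45 mg/dL, non-smoker, non-diabetic) reaches the same predicted
   risk; it is computed by monotone inversion of the risk function over
   age, and **vascular ageing** is vascular age minus chronological age.

3. **Rank-based cohort statistics.** Median [25th; 75th percentile]
   summaries (type-7 quantiles), two-sided Mann–Whitney rank-sum
   comparisons (exact for small tie-free samples, tie-corrected normal
   approximation otherwise), Pearson chi-squared for categorical
   variables, Spearman correlations (exact permutation p at n ≤ 8),
   and HOMA-IR = insulin [µIU/mL] × glucose [mmol/L] / 22.5.

4. **A synthetic cohort generator** that emulates the two-group study
   structure (36 controls vs 24 cases by default) with a configurable
   methylation–age relationship and group clock offset, so the whole
   pipeline is testable without patient data.

## Worked example

```python
from epiaging import (MethylationProfile, predict_epigenetic_age,
                      age_acceleration, RiskFactorProfile, assess_profile,
                      homa_ir, glucose_mgdl_to_mmol)

p = MethylationProfile("subj-01", elovl2_c7=52.4, c1orf132_c1=48.9,
                       trim59_c7=41.0, klf14_c1=8.6, fhl2_c2=27.3)
epi = predict_epigenetic_age(p)
print(round(epi, 1), round(age_acceleration(epi, 46.0), 1))
# 36.5 -9.5   -> this subject is 9.5 years epigenetically younger

r = RiskFactorProfile(age=46.0, sex="female", sbp=141.0,
                      on_htn_treatment=False, smoker=False, diabetic=False,
                      total_chol=196.0, hdl_chol=48.0)
res = assess_profile(r)
print(round(100 * res.risk_10yr, 1), round(res.vascular_age, 1),
      round(res.vascular_ageing, 1))
# 5.1 54.4 8.4  -> 5.1% 10-year CVD risk; the untreated SBP of 141 mmHg
#                  makes her vasculature behave like that of a 54-year-old

print(round(homa_ir(24.9, glucose_mgdl_to_mmol(100.0)), 1))
# 6.1  -> insulin-resistant (HOMA-IR above the usual ~2.5 cut-off)
```

The same analyses run from the shell over a cohort CSV/TSV
(column schema in `epiaging/io.py`):

```sh
epiaging simulate --seed 17 --out cohort.csv       # synthetic cohort
epiaging epiage   --in cohort.csv --out ages.tsv   # clock + acceleration
epiaging frs      --in cohort.csv --out frs.tsv    # risk, vascular age
epiaging compare  --in cohort.csv --out table1.tsv # group summary table
epiaging run-all  --in cohort.csv --out-dir reports/
```

`compare` and `run-all` print p-values the way clinical tables do:
`ns` (p ≥ 0.05), `=0.0xx`, or `<0.001`; raw p-values are always in the
machine-readable output.

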