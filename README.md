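# pcrad

Predicting **pathologic complete response (pCR)** to neoadjuvant chemotherapy
in breast cancer from pre-treatment DCE-MRI radiomics combined with clinical,
radiological and histological covariates.

The package is aimed at medical-physics and imaging-biomarker researchers who
want a fully reproducible, testable version of this analysis chain. The
original study cohort (60 patients: 20 complete responders, 40
non-responders) is private, so a first-class synthetic-data module generates
cohorts with the published group-conditional summary statistics — and lesion
phantoms with known geometry and texture — so every stage can be exercised
and validated end to end.

## What it computes

1. **Radiomic features** from a lesion mask on two DCE-MRI channels (the
   post-contrast dynamic image and the subtracted image), after IBSI-style
   preprocessing — intensity normalization to mean 0 / sd 100, isotropic
   resampling to 0.90 mm cubes (cubic b-splines; nearest-neighbour for the
   mask) and fixed-bin-count discretization with Ng = 8:
   - F1 sphericity `(36 π V²)^{1/3} / A` (triangulated mesh surface),
   - F2 kurtosis `m₄ / m₂²` (Pearson, non-excess),
   - F3 GLDM dependence variance,
   - F4 GLRLM long-run high-gray-level emphasis (mean over the 13 unique 3D
     directions),
   - F5 GLSZM high-gray-level zone emphasis (26-connected zones).
2. **Univariate statistics**: Welch two-sample t-tests (from raw data or from
   printed n/mean/sd summaries), exact r×c Fisher tests by Freeman–Halton
   enumeration, Spearman correlation screens.
3. **Feature reduction**: L1-penalized logistic regression (cyclic coordinate
   descent on IRLS approximations, warm-started path), with the penalty λ
   chosen by minimum mean leave-one-out cross-validated deviance
   (`LassoLogisticCV`, a scikit-learn-style selector).
4. **Exhaustive model search** (`ExhaustiveSubsetSearch`): every non-empty
   covariate subset of a variable group — G1 (clinical/radiological), Rad
   (F1–F5), Hist (Ki67, ER, PgR, HER2), NoRad = G1 ∪ Hist, All — fitted with
   logistic regression, linear SVR or random forest and ranked by the average
   of leave-one-out and 30-fold (leave-two-out) cross-validated AUCs. Each
   model gets a DeLong confidence interval and a Mason–Graham p-value against
   AUC = 0.5 (via the Mann–Whitney identity), Benjamini–Hochberg adjusted
   across the run. Per-covariate importance is the inclusion frequency in the
   six best models, and logistic coefficients are aggregated across all
   fitted subsets as `m_j = Σᵢ m_ij σ_ij⁻² / Σᵢ σ_ij⁻¹` with |m_j| > 1 read
   as a relevant signed association.

## Worked example

```python
import pcrad

cohort = pcrad.generate_cohort(pcrad.SyntheticConfig(seed=7))   # 60 subjects
report = pcrad.make_table1_report(cohort)
print(report.head(4).to_string(index=False))

search = pcrad.run_group_search(
    cohort, pcrad.standard_groups()["Hist"], classifier="logit", seed=7
)
spec, perf = search.best6[0]
print("+".join(spec.subset), round(perf.auc_mean, 3), perf.ci)
```

prints (exactly, for seed 7):

```
covariate  test   responders nonresponders        p
      Age welch 48.6 (±10.8)  52.4 (±11.7) 0.217956
      ADC welch   827 (±236)    857 (±202) 0.633501
  PET_SUV welch 7.06 (±5.15)  4.55 (±4.54) 0.073426
     Ki67 welch   38 (±20.5)  19.2 (±11.9) 0.000833
Ki67+ER+PgR+HER2 0.893 (0.788920311091612, 1.0)
```

i.e. on this synthetic cohort the proliferation index Ki67 separates the
groups strongly (Welch p ≈ 8 × 10⁻⁴, matching the planted group difference),
and the best histology-only model reaches a dual-CV mean AUC of 0.89 with a
DeLong 95% interval of roughly [0.79, 1.00]. The aggregated logistic
coefficients for this run (`search.m_agg`) give Ki67 ≈ +3.0 and ER ≈ −3.0:
higher proliferation correlates with response, higher estrogen-receptor
expression with non-response, as planted.

The same pipeline runs from the shell:

```bash
pcrad run --out run1 --seed 7            # simulate → table1 → reduce → search → report
pcrad simulate --out run2 --seed 3 --n-phantoms 2
pcrad extract --out run2                 # F1..F5 from the phantom volumes
```

Every stage writes its artifact plus a manifest (parameters, seed, version);
identical configurations reproduce byte-identical outputs.

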