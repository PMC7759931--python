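# ctradiomics

**CT radiomic heterogeneity vs circulating tumor DNA in longitudinal
oncology cohorts.**

Circulating tumor DNA (ctDNA) quantified as a mutant allele fraction
(ctDNA*maf*) in blood plasma and radiomic texture analysis of routine CT both
track tumor burden over time — but through different physics. The scientific
question this package operationalises is whether CT heterogeneity features
of a tracked lesion predict ctDNA*maf*, and crucially whether they do so
*beyond lesion volume*, which confounds both measurements. It is written for
biostatisticians and imaging scientists who want the full analysis chain as
tested, reusable code: 3D feature extraction, mixed-model screening
calibrated by spike-in random predictors, volume-controlled inference, a PCA
radiomics signature, a correlation-matched Monte-Carlo null test, and
ctDNA/LDH/signature association models — all runnable end-to-end on
synthetic cohorts with the statistical structure such studies report.

## The statistics at the core

Every inferential step uses the patient random-intercept linear mixed model

    log(ctDNAmaf)_ij = x_ij' β + b_i + e_ij,
    b_i ~ N(0, σ²_patient),  e_ij ~ N(0, σ²_resid),

fitted by profiled REML/ML (closed-form per-patient GLS; Satterthwaite df
for Wald t; marginal R² = Var(Xβ̂)/(Var(Xβ̂)+σ²_patient+σ²_resid)). Feature
screens spike in 100 random Gaussian predictors and apply Benjamini–Hochberg
FDR to the combined real+random p-value set, so the spike-ins calibrate the
multiplicity correction. Volume-adjusted screens add a likelihood-ratio test
of each feature against the volume-only model; the five features with the
smallest LRT p-values define a signature

    S = Σ_k  w_k · z(t_k(f_k)),

the first principal component of the standardized transformed features. Its
significance beyond volume is assessed against thousands of simulated
feature sets with the real features' covariance (volume correlation
included, response correlation zero by construction), re-running the top-5
selection inside every simulated dataset so the null carries the same
selection bias as the real statistic.

Feature extraction follows an absolute-bound configuration: 1 mm isotropic
resampling, 128 gray levels over [−400, 400] HU (32 for zone features), and
GLCM / GLRLM / GLZLM / NGLDM texture families pooled over the 13 unique 3D
directions — every texture feature is verified against independent
brute-force enumeration oracles in the test suite.

## Worked example

Run the whole pipeline on a synthetic cohort (15 patients, ~70 visits,
volume-driven ctDNA, volume-correlated features):

```bash
ctradiomics run --seed 1 --n-null 200 --out demo_out
```

which prints

```
pipeline complete: demo_out/ (null-test p_r2=0.9154, p_lrt=0.9104)
```

and writes `screen_unadjusted.csv`, `screen_volume_adjusted.csv`,
`selection.json`, `signature.json`, `null_scatter.csv`, `association.json`
and a `manifest.json` recording seeds and the config hash. Reading those
numbers: in this cohort the features predict ctDNA*maf* strongly on their
own (at seed 1 the unadjusted screen flags all 9 real features, with lesion
volume ranked first), but they carry **no** information beyond lesion
volume — the generator builds them that way — so the Monte-Carlo null test
correctly returns a large empirical p (0.92): the real top-5 statistic sits
inside the cloud of 200 volume-matched random feature sets. The association
report in `association.json` shows the generator's triangle: the radiomics
signature and LDH each predict ctDNA*maf* (marginal R² = 0.55 and 0.44
here) while being nearly independent of each other (R² = 0.03) — the
complementary-biomarker configuration.

The same stages are available as library calls (`generate_cohort`,
`extract_all`, `screen_features`, `lasso_select` / `stepwise_r2`,
`build_signature`, `null_reference_test`, `association_triangle`) and as
subcommands (`simulate`, `extract`, `assemble`, `screen`, `run`); see
`docs/methods.md` for the models, defaults, and numerical choices.

Extract features from a NIfTI volume/mask pair:

```bash
ctradiomics extract --volume lesion.nii.gz --mask roi.nii.gz \
    --bins 128 --zone-bins 32 --range -400 400 --resample 1.0 \
    --out features.csv
```

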