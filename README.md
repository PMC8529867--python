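# deltarad

Filtration-histogram CT texture analysis and delta-radiomics survival
modelling, packaged as a tested, reusable pipeline with a synthetic
phantom/cohort generator.

## The problem

In metastatic melanoma treated with PD-1 inhibitors, intra-tumour
heterogeneity visible on contrast-enhanced CT is a candidate imaging
biomarker of outcome.  One established way to quantify it is
*filtration-histogram* texture analysis: each target lesion's ROI is
band-pass filtered with a Laplacian-of-Gaussian (LoG) kernel at spatial
scale filters (SSF) of 2–6 mm (2 = fine, 3–5 = medium, 6 = coarse; SSF = 0
means no filtration), and the filtered values inside the ROI are reduced to
six histogram statistics — mean, standard deviation (SD), entropy, mean of
positive pixels (MPP), skewness and kurtosis — over the integer-binned
histogram.  *Delta-radiomics* adds the percentage change of each feature
between baseline and the first post-therapy scan,

```
perc-Var = 100 · (var_pre − var_post) / var_pre ,
```

computed per lesion and averaged per patient.  Patient-level features then
enter a survival workflow: LASSO-Cox feature selection (10-fold
cross-validation, penalty at minimum CV deviance, best marker by largest
|coefficient|), multivariate Cox proportional-hazards models alongside
dichotomized clinical covariates (LDH > 1.5 × ULN, LDH percentage change
> 20 %, ≥ 3 metastatic sites), and Kaplan–Meier stratification at a median
or fixed cutoff with a log-rank test.

The package is aimed at imaging researchers who want a transparent,
scriptable implementation of this workflow — and, because clinical imaging
cohorts are rarely shareable, it ships a first-class synthetic study
generator: lesion phantoms whose heterogeneity is controlled by object
size, density and number, paired baseline/post-therapy images with a
controllable entropy shift, and survival times drawn from an exponential
proportional-hazards model `h(t) = λ₀·exp(βᵀx)` planted on the extracted
features.

## Worked example

```python
from deltarad import phantoms, survival

cohort = phantoms.generate_cohort(phantoms.CohortSpec(n_patients=150, seed=3))
report = survival.run_endpoint_analysis(cohort.patient_table, "OS", seed=3)

print("LASSO best baseline feature:", report.lasso_baseline.best_feature)
fit = report.cox_fits["kurtosis_ssf2"]
row = fit.summary.loc["kurtosis_ssf2"]
print(f"kurtosis (SSF=2): HR={row.hr:.2f} "
      f"95% CI {row.ci_low:.2f}-{row.ci_high:.2f} p={row.p:.2g}")
km = report.km_results["kurtosis_ssf2@median"]
print(f"KM medians above/below cutoff: {km.median_above:.1f} / "
      f"{km.median_below:.1f} months, log-rank p={km.p_value:.2g}")
```

prints

```
LASSO best baseline feature: kurtosis_ssf2
kurtosis (SSF=2): HR=0.56 95% CI 0.42-0.74 p=4.1e-05
KM medians above/below cutoff: 43.4 / 17.1 months, log-rank p=0.00011
```

The default cohort plants a protective baseline-kurtosis effect
(β = −0.6 per SD) and a delta-entropy effect (β = +0.6 per SD): the fitted
hazard ratio below 1 means higher kurtosis predicts longer survival, and
the Kaplan–Meier split at the cohort median separates the two prognostic
groups by about 26 months of median overall survival.

The same workflow runs disk-to-disk through the CLI:

```sh
deltarad synth --n-patients 40 --seed 1 --out study/
deltarad run --manifest study/manifest.json --clinical study/clinical.csv --out reports/
```

which writes Cox model tables (`table2_like.csv`, `table4_like.csv`), KM
stratification tables (`table3_like.csv`, `table5_like.csv`), the LASSO
paths (`lasso_path.json`), the per-patient feature table and the exact
config used.  `deltarad features`, `delta`, `survive` and `validate` expose
the individual stages.

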