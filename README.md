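# metaboplsda

Validated PLS-DA discriminant analysis for targeted serum amino-acid
panels, with repeated double cross-validation, permutation testing, VIP
variable selection and synthetic cohort simulation.

## The problem

Targeted metabolomics studies of frailty and type 2 diabetes compare a
panel of circulating amino acids and derivatives (here: 37 analytes,
µmol/L) between a case group (66 frail/pre-frail older adults with
diabetes) and a control group (30 robust, non-diabetic peers). With many
correlated predictors and few samples, the standard chemometric approach
is **partial least squares discriminant analysis (PLS-DA)**: the binary
class label *y* ∈ {0, 1} is regressed on the autoscaled concentration
matrix **X** through a small number of latent variables (LVs) — directions
**w** maximising cov(**Xw**, *y*) — extracted by the NIPALS deflation

> w_a ∝ X_aᵀ y_a, t_a = X_a w_a, q_a = t_aᵀ y_a / t_aᵀ t_a,
> X_{a+1} = X_a − t_a p_aᵀ, y_{a+1} = y_a − q_a t_a.

Because such models classify noise well if unchecked, the workflow is
validated by **repeated double cross-validation (DCV)** — an inner
stratified 5-fold loop selects the LV count by minimising held-out
misclassifications, an outer 5-fold loop scores the refitted model on
untouched samples, and the whole procedure is repeated (default 20×) with
fresh splits — and by **permutation tests**: the class labels are shuffled
B = 1000 times, the full DCV pipeline is re-run on each shuffle, and the
observed figures of merit are located in the resulting null
distributions. Three figures of merit are tracked on the pooled outer
predictions:

- **NMC** — number of misclassifications,
- **AUROC** — Mann–Whitney rank probability that a random case outscores
  a random control,
- **DQ2** — a discriminant Q² in which residuals overshooting the label
  in the correct direction are not penalised.

Discriminant analytes are read off the final model via **variable
importance in projection**: VIP_j = √(p · Σ_a SSY_a w²_ja / Σ_a SSY_a)
with SSY_a = q_a² t_aᵀ t_a, normalised so Σ_j VIP_j² = p; analytes with
VIP > 1 form the discriminant metabotype.

Since the underlying clinical data are not public, the package ships a
calibrated generator (`synthetic_cohort`) that simulates cohorts from the
published class-conditional means ± SDs of the nine discriminant analytes
plus a 28-analyte null background, together with clinical covariates
(age, sex, BMI, SPPB, disease count) for the descriptive statistics
module.

## Worked example

```sh
metaboplsda simulate --seed 42 --out cohort.csv
metaboplsda dcv --in cohort.csv --seed 7 --out dcv.json
metaboplsda permtest --in cohort.csv -b 200 --seed 7 --out perm.json
```

prints

```
wrote 96 x 37 cohort to cohort.csv
outer correct classification: 93.2 ± 1.6%
p(NMC)=0.004975  p(AUROC)=0.004975  p(DQ2)=0.004975
```

`dcv.json` holds the full aggregates — calibration 98.6 ± 0.3%, inner
94.0 ± 0.9% and outer 93.2 ± 1.6% correct classification (mean ± SD over
20 repetitions; 94.8% for cases, 89.7% for controls in the outer loop),
with pooled outer NMC 6.5 ± 1.5, AUROC 0.980 ± 0.005 and DQ2 0.67 ±
0.02. All three permutation p-values sit at the B = 200 estimator floor
1/201 ≈ 0.005: the classification is far outside its label-shuffled null.

The same in Python, continuing to the final model and VIP selection:

```python
import numpy as np, metaboplsda as mp

ds = mp.generate(mp.default_template(), 66, 30, seed=42)
a = mp.select_components_inner(ds.X, ds.y, mp.DCVConfig(seed=7), np.random.default_rng(7))
model = mp.pls_fit(ds.X, ds.y, a, analyte_names=ds.analyte_names)
print(mp.vip(model).to_frame().head(7))
```

```
           analyte       vip
           Taurine  3.167530
     Glutamic acid  2.435007
 3-methylhistidine  2.049201
         Sarcosine  1.773643
           Alanine  1.607315
      Ethanolamine  1.546910
          Arginine  1.248195
```

The VIP > 1 set recovers seven of the nine planted discriminant analytes
— exactly those with a standardised class difference ≥ 0.69; the two weak
effects (tryptophan, ornithine, standardised differences ≈ 0.2) are below
the detection limit of a 96-sample cohort (see `docs/methods.md`).

`metaboplsda report --seed 3 --out run/` chains simulation, DCV, the
permutation test and VIP into a schema-versioned `report.json` with
plot-ready TSV exports (LV1/LV2 scores for the class-separation plot,
binned null histograms with the observed markers), and
`metaboplsda table1 --in clinical.csv --out table1.json` reproduces the
descriptive cohort comparisons (KS-gated pooled-t / Mann–Whitney U for
continuous covariates, Yates-corrected χ² for sex).

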