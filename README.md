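# crgmet

Metabolite associations with **compensatory renal growth (CRG)** — the
hypertrophy of benign kidney parenchyma in response to nephron loss or
tumor burden.  In patients undergoing nephrectomy for renal cell
carcinoma, CRG can be surrogated from routine imaging as the ratio of
contralateral to ipsilateral-benign parenchyma volume (VC/VI); its
long-term counterpart (LT-CRG) is the fold change of the remaining
kidney's volume after radical nephrectomy.  This package implements, as a
tested and reusable pipeline, the analysis chain that links benign- and
tumor-tissue metabolite abundances (and clinical covariates) to CRG:

- **volumetry** — CRG and LT-CRG response construction with
  dual-observer concordance QC (observer CRG ratio outside (0.75, 1.25)
  excludes the patient; concordant pairs are averaged);
- **preprocess** — median normalization of metabolite abundances,
  elimination of metabolites with >75% below-LOD measurements,
  minimum-detected-value imputation, dummy coding of covariates, design
  assembly;
- **opls** — a from-scratch NIPALS OPLS regression (one predictive
  component plus orthogonal signal correction) exposed as a
  scikit-learn estimator, with VIP variable importance, R²/Q²,
  8-fold cross-validation and a response-permutation model test;
- **association** — univariable reference regressions per variable,
  Benjamini–Hochberg FDR, and the dual significance criterion
  *VIP > 1 and adjusted p < 0.05*;
- **enrichment** — directional sub-pathway (metabolite-set) enrichment
  over the signed VIP ranking, weighted Kolmogorov–Smirnov running sum
  with a label-permutation null;
- **contrast** — the detrended two-tissue regression
  `CRG* ~ x_tumor* + x_benign*` comparing |β| contributions for a single
  metabolite;
- **synthetic** — a cohort generator emulating the study conditions
  (49-patient imaging scale, 877 metabolites of which 577 identified,
  heavy below-LOD censoring, clinical covariate marginals, planted
  metabolite effects and enriched sub-pathways) with serialized ground
  truth for recovery testing.

## The model

For centered (and by default unit-variance scaled) design **X** and
centered response **y**, each orthogonal component is extracted by the
NIPALS recursion

```
w ∝ Xᵀy,  t = Xw,  p = Xᵀt/(tᵀt)
w_o ∝ p − (wᵀp)w,  t_o = Xw_o,  p_o = Xᵀt_o/(t_oᵀt_o),  X ← X − t_o p_oᵀ
```

and a final single predictive PLS component is fitted to the filtered
matrix.  Variable importance is the VIP score, which for the single
predictive component reduces to `VIP_j = √K·|w_j|` (so mean VIP² = 1 and
VIP > 1 flags above-average contributors); the signed per-variable effect
is `p_j·c` with `c` the response loading.  The number of orthogonal
components is chosen automatically: components are added while
cross-validated Q² improves by more than 0.01 (capped at 9).  Model
validity is assessed by ranking the real cross-validated RMSE within the
RMSEs of 1,000 fits to permuted responses.

## Worked example

```python
from crgmet import RunConfig, generate_dataset, run_analysis

data, truth = generate_dataset(seed=0)           # 52 imaged patients, 877 metabolites
config = RunConfig(analysis="benign_preop", seed=0,
                   n_perm_opls=1000, n_perm_enrich=10000)
result = run_analysis(config, data)

print(f"patients: {result.manifest['n_patients']}, variables: {result.manifest['n_variables']}")
print(f"metabolites retained: {result.manifest['n_metabolites_retained']} / 877")
print(f"R2Y = {result.model.r2y_:.3f}, Q2 = {result.model.q2_:.3f}, "
      f"permutation p = {result.permutation.p_value:.4f}")
print(result.class_counts())
print(result.association.nlargest(3, "vip")[["name", "vip", "effect", "fdr_p", "class"]])
print(result.enrichment.nsmallest(3, "fdr_p")[["sub_pathway", "direction", "es", "fdr_p"]])
```

prints

```
patients: 49, variables: 754
metabolites retained: 732 / 877
R2Y = 0.860, Q2 = 0.311, permutation p = 0.0010
{'not_significant': 548, 'suggestive': 192, 'significant_positive': 14}
        name      vip   effect    fdr_p                class
10455_benign 4.088254 0.004454 0.000002 significant_positive
10315_benign 3.977620 0.004280 0.000003 significant_positive
10087_benign 3.969435 0.004410 0.000003 significant_positive
             sub_pathway direction       es    fdr_p
    carnitine metabolism  positive 0.760576 0.001866
fatty acid, medium chain  positive 0.781764 0.001866
 fatty acid, monohydroxy  positive 0.700995 0.001866
```

Three patients of 52 fell to observer-concordance QC, the detection
filter kept 732 of 877 metabolites, and the benign-tissue fit calls 14
metabolites significantly positively associated with CRG (the planted
block), with the planted fatty-acid/carnitine sub-pathways enriched among
positive associations and the permutation test confirming the model
predicts far better than chance.

The same pipeline is scriptable from the shell:

```bash
crgmet synthesize --n-patients 52 --seed 0 --out-dir data/
crgmet run-all --data-dir data/ --out-dir results/ --seed 0
crgmet contrast --data-dir data/ --metabolite 10455
```

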