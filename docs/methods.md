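# Methods

## Responses: CRG and LT-CRG

Pre-operative compensatory renal growth is the volume ratio VC/VI
(contralateral kidney parenchyma over ipsilateral benign parenchyma,
both in cc); LT-CRG is the fold change of the remaining kidney's volume
between follow-up and baseline after radical nephrectomy.  Patients
measured by two observers pass a concordance check on the ratio of the
two observers' CRG values against the open interval (0.75, 1.25);
failures are excluded from *all* analyses, survivors get the average of
the two CRG values (the ratios are averaged, not the volumes).  The band
is asymmetric on the ratio scale (1/1.25 = 0.8 ≠ 0.75), so the test is
applied to a fixed, configurable observer order; swapping observers can
flip the decision for ratios between 0.75 and 0.8 (and between 1.25 and
1/0.75).  Single-observer patients bypass the check.  The follow-up
interval is stored but not used as a covariate.

## Preprocessing

Per metabolite: divide by the median of *detected* (not below-LOD)
values, eliminate the metabolite if strictly more than 75% of its
measurements are below LOD, then impute remaining below-LOD cells with
the per-metabolite minimum detected normalized value.  The minimum is
per metabolite, not global: a cross-metabolite minimum would inject
scale artifacts.  Pipeline order is normalize → filter → impute; the
filter only reads the LOD mask, which imputation preserves, so this
order is equivalent to imputing first.  Metabolites with no detected
values at all are left unscaled and necessarily fall to the filter.

Categorical covariates are dummy-coded against declared reference levels
(gender=female, race=afro-american, T stage=pT1a, grade=2, AJCC=1,
binary comorbidities=no); nephrectomy type and imaging modality are
never covariates, and N/M stage information enters only through the
composite AJCC stage.  Zero-variance columns (e.g. a stage level with no
patients) are dropped with a warning, since projection weights are
undefined for them.  Missing continuous covariates fail loudly.

## Design scaling

The design matrix is mean-centered, and by default in the analysis
pipeline also scaled to unit variance (`RunConfig.scaling =
"center_scale"`; the lower-level `assemble_design` default is
center-only).  The projection weight is proportional to per-column
covariance with the response, so with raw-scale columns a single
large-variance clinical covariate (tumor volume, in cc, sd in the
hundreds) dominates the component regardless of its correlation with
the response, and metabolite VIPs become meaningless.  Unit-variance
scaling is also the default behavior of the standard OPLS
implementations used for this kind of metabolomics analysis and is the
only choice under which a metabolite can plausibly attain the top VIP
of a mixed metabolite/covariate design.  Both options are exposed
because VIP magnitudes depend on this choice.

## OPLS

One predictive component plus `n_ortho` orthogonal components via the
NIPALS recursion (see README for the update equations).  `n_ortho` is
selected automatically by adding components while cross-validated Q²
improves by more than ΔQ²_min = 0.01, up to 9; this selection is the
single largest lever on reported VIPs and is recorded in every manifest.
VIP uses the predictive component only by default
(`VIP_j = √K·|w_j|`, so ΣVIP² = K exactly); a "total" variant including
orthogonal components weighted by their share of explained response
variance is available.  The signed per-variable *effect* is the
predictive loading times the response loading (`p_j·c`), equivalent in
sign to the OPLS regression coefficient.

Cross-validation uses a seeded shuffle into 8 (or fewer, if patients are
scarce) near-equal folds; each fold refits with the same `n_ortho` and
per-fold centering; Q² = 1 − PRESS/TSS on held-out predictions.

### Permutation validation

Each of `n_perm` (default 1,000) seeded permutations of the response is
evaluated with the *same* fold split and `n_ortho`, recording its mean
cross-validated held-out RMSE.  The primary p-value is the plus-one
empirical rank of the real mean CV RMSE in that null sample — under an
uninformative design the real response is exchangeable with its
permutations, so this p-value is exactly uniform and the test is
calibrated.  Training-error comparisons are avoided deliberately: with
hundreds of variables and ~50 patients the training RMSE of any fit,
permuted or not, is near zero and carries no information.  A two-sided
Wilcoxon rank-sum p between the per-fold real RMSEs and the permuted
RMSEs is reported alongside for reference, but the 8 fold RMSEs share
one data set, violating the test's independence assumption, so it is
not used for calls.  Permutations reuse the `n_ortho` selected on the
unpermuted fit (re-selection per permutation is a config flag).

## Associations and significance calls

Per variable, an ordinary least-squares fit of the response on that
variable alone supplies the reference slope and two-sided t-test p.
Benjamini–Hochberg adjustment runs across all variables of one analysis
jointly (metabolites plus covariates); the four analyses are separate
FDR families.  Benjamini–Yekutieli is available via the method argument.
Calls: *significant* (positive/negative by effect sign) requires VIP > 1
and adjusted p < 0.05; VIP > 1 with adjusted p ≥ 0.05 is *suggestive*;
everything else *not significant*.

## Sub-pathway enrichment

Only identified metabolites participate.  The ranking statistic is
VIP·sign(effect), sorted descending (ties broken by compound id), which
preserves the descending-VIP order within each direction while giving
the directional reading: positive associations at the top, negative at
the bottom.  For each sub-pathway with ≥ 3 members the weighted KS
running sum (member increments |s|^w normalized over members, default
w = 1; non-member decrement 1/(N−n)) yields the positive-direction score
(path maximum) and negative-direction score (path minimum).  The null
permutes set membership labels over the fixed ranked list — permuting
samples would require refitting the multivariable model per draw and
would confound model and set nulls.  Empirical p-values use the plus-one
convention with a small tie tolerance; BH-FDR runs across all
(set, direction) pairs of the analysis.

## Two-tissue contrast

For one metabolite, the response and both tissue abundance series are
linearly detrended over the patient-index order of the input table and
jointly regressed: `CRG* ~ x_tumor* + x_benign*`.  The result reports
both coefficients and which |β| is larger.  With cross-sectional data
detrending has no natural ordering, so the operation is order-sensitive
by construction; the ordering is the stored patient order and is
recorded with the run.  Near-collinear predictors (|r| > 0.999) are
rejected as non-identifiable.  Frisch–Waugh equivalence with partialled
two-stage regression is enforced by test.

## Synthetic cohorts

The generator emulates the study conditions rather than any particular
data set: 52 imaged patients (so that ~49 survive observer QC), 877
metabolites with 577 identified and annotated to a 28-term sub-pathway
catalog, covariates drawn to the published cohort marginals (age
60 ± 11.6 clipped to 37–86, 79.6% male, 63.3% hypertension, lognormal
tumor volume matching mean 233.7/sd 224.1 cc, the printed stage and
grade frequencies), and per-observer volume noise with CRG log-sd 0.095 —
chosen so the expected share of dual-observer ratios outside
(0.75, 1.25) matches the observed 3/42 exclusion rate.

Dependence runs through a single latent patient trait G (the "CRG
drive"): each planted metabolite's standardized log-abundance loads on G
with coefficient β, members of a planted sub-pathway share an additional
set factor (fraction 0.15 of variance), the benign and tumor residuals
of the same compound share a patient-level factor (fraction 0.5 of
residual variance — matched tissue pairs co-vary, which is precisely
what makes fold-change analysis informative), and log CRG is linear in G
with noise scaled so G explains R² = 0.75 of it.  A planted metabolite's
population correlation with measured CRG is then approximately
β·√R²·(lognormal attenuation ≈ 0.94)·(observer attenuation ≈ 0.85).
Abundances are exponentiated (log-sd 0.5) because the pipeline operates
on the normalized, not logged, scale.

Censoring marks the lowest per-metabolite quantile as below LOD.  By
default a rarely-detected tail (16.1% of benign, 17.5% of tumor
metabolites, excluding effect carriers, with the rare probability
rescaled so the cohort-level share holds) draws its BDL fraction from
U(0.78, 0.97) — always failing the 75% filter — while the bulk draws
from 0.7·Beta(0.7, 5); the expected retention is thereby 736/877 benign
and 724/877 tumor, the study's reported scale.  A single `lod_quantile`
can override this (0 disables censoring).

The default planted truth mirrors the study's qualitative findings:
three benign fatty-acid/carnitine sub-pathways whose members all shift
positively (13 members at β ≥ 0.85 including one standout at 0.95, the
rest mild at 0.35), two strongly positive tumor sub-pathways plus
unidentified positives, four coordinated weakly negative tumor
sub-pathways (β = −0.25: enrichable but individually sub-significant),
one strong sole tumor negative (β = −0.80), and three metabolites with
anti-correlated benign/tumor loadings whose fold change associates with
CRG although neither tissue alone is significant.  The strong-β values
are dictated by arithmetic, not preference: surviving BH across ~750
tests at n ≈ 49 requires |r| ≳ 0.55, i.e. β ≈ 0.9 through the
attenuation chain above.  Mild and weak loadings sit deliberately below
that bar.  What these cohorts do *not* emulate: covariate–metabolite
confounding, batch/drift structure, heteroscedastic platform noise, and
non-lognormal abundance shapes — pipeline success here shows the
statistics behave as designed, not that any particular biological claim
transfers to real data.

## Calibration experiments

`crgmet.validation` isolates three operating characteristics on
metabolite-only designs with the noise-free-response CRG: permutation
type-I error on 200 null cohorts (n = 49, 500 metabolites, 199
permutations each, `n_ortho = 0` so the measured property is the
permutation p itself rather than component selection, which conditions
on the observed response and would bias the null slightly); VIP-rank
recovery of 10 planted β = 0.5 metabolites among 500 noise columns over
50 seeds; and FDR-controlled detection of one planted coordinated
sub-pathway over 50 seeds.  Problem sizes (replicate counts, permutation
counts) are chosen to estimate each rate to a few percent.

## Numerical choices and degenerate inputs

Unit-norm weights with a guard against numerically zero Xᵀy; orthogonal
extraction stops early when no orthogonal variation remains; constant
responses, zero-variance design columns, folds with fewer than two
patients, n < 3 detrending and n = 2 univariable fits are all rejected
with explicit errors.  Enrichment p-values use a 1e-12 tie tolerance so
arrangements sharing an extremum up to float round-off count as equally
extreme.  All fold assignments, permutations and generators take
explicit seeds; identical configuration and seed reproduce outputs byte
for byte, and every output embeds the SHA-256 manifest hash of its
configuration.

## Known limitations

Exact reproduction of the original study's printed VIPs and adjusted
p-values requires its supplementary cohort tables, which are not
distributed with this package; the acceptance script therefore reports
the synthetic analogues of those quantities.  At ~50 patients the
number of dual-criterion calls varies substantially between cohort
realizations (the acceptance script reports medians over three
replicates for this reason).  The OPLS implementation is single-response
with one predictive component; multi-block and discriminant variants are
out of scope.
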