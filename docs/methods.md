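# Methods

`msinflam` implements a composite-biomarker analysis for cross-sectional
neuroimmunology cohorts: blood acute phase reactants (APRs) and CSF immune
analytes are standardised into covariate-adjusted Z-score residuals,
aggregated into correlation-derived cluster scores, and related to
diagnosis group and MS severity scales. A synthetic-cohort generator with
known ground truth makes every stage testable without clinical data. This
note records the model, the defaults and why, the numerical choices, and
what the synthetic validation does and does not establish.

## The analysis model

**Visit summarisation.** Repeated visits are treated as exchangeable
replicates. Stability is screened with the one-way random-effects
intraclass correlation, unbalanced-design form:

    ICC = (MSB − MSW) / (MSB + (k0 − 1)·MSW),
    k0  = (N − Σ nᵢ²/N) / (a − 1)

where MSB/MSW are the between/within-subject ANOVA mean squares over `a`
subjects and `N` observations. The one-way variant is the right estimand
because visits carry no rater or order structure. The estimate is reported
unclipped (it may be negative). Analytes with ICC ≤ 0.8 are *flagged*, not
excluded: all available visits are averaged per subject regardless, and
the flag is informational. Severity scales (MSSS, ARMSS, MS-DSS, consumed
as input columns; never computed from EDSS here) take the chronologically
last non-missing value per subject.

**Standardisation.** Each analyte is shifted by `1 − min(x)` when its
minimum is ≤ 0 (ESR and CRP can be exactly zero), Box-Cox transformed with
λ maximising the profile log-likelihood on the grid −3…3 in steps of 0.01
(deterministic; ties resolve to the smallest λ), then Z-scored with the
n−1 standard deviation on the pooled HD+MS sample. Pooled rather than
within-group standardisation is used because the downstream HD-vs-MS
comparisons are made on a common scale.

**Covariate adjustment.** Per analyte, `Z ~ diagnosis + race + age + sex +
covariate×covariate interactions` is fit by OLS. A covariate term is
retained iff its type-II ANOVA p-value (model comparison respecting
marginality, full-model mean-squared-error denominator) is below 0.05; a
selected interaction always brings its main effects. The reduced model —
diagnosis is always kept — is refit and only the fitted covariate effects
are subtracted:

    residual = Z − (fitted covariate terms)
             = intercept + fitted diagnosis effect + OLS error,

an exact algebraic identity that the test suite asserts at 1e−10. Sex and
race are reference-coded against their largest category; race levels with
fewer than 5 subjects are pooled into "Other" (sparse strata otherwise
produce singular designs, which raise an error naming analyte and term).
Diagnosis×covariate interactions are deliberately excluded: the candidate
set is interactions *among* the confounders, keeping the diagnosis effect
a pure group contrast.

**Polarity and clustering.** Negative APRs (serum albumin, iron,
transferrin) fall during inflammation, so their residuals are multiplied
by −1 before clustering. Because residualisation is linear, flipping
before or after adjustment yields identical residuals (asserted at 1e−10);
the order is therefore a non-issue and the default flips after. Clusters
are connected components of the graph joining two same-compartment
analytes when their pairwise-complete Pearson r ≥ 0.3 with raw p < 0.05.
Blood clusters are derived on all patients, CSF clusters on MS patients
only. The default *frozen* mode instead uses the published composite
layout (three blood clusters; innate-myeloid and humoral CSF clusters;
sCD27 and CSF albumin standalone): the CSF split is a biological choice —
empirically nearly all CSF analytes inter-correlate — so data-driven CSF
derivation is opt-in. The 0.3 threshold is a package default exposed in
configuration; no principled universal value exists for "correlated with
each other", and 0.3 reproduces the expected blood partition at realistic
loadings. Cluster scores are per-subject means of non-missing member
residuals (missing only when all members are missing), with contributing
counts recorded.

**Inference.** Marker-level HD-vs-MS differences use the diagnosis F-test
from the linear model; cluster-score HD-vs-MS differences use the
equal-variance unpaired t-test. Blood×CSF cluster associations use Pearson
correlation within the MS cohort (and RRMS/PMS sub-cohorts); cluster ×
severity associations use Spearman only, because the severity scales are
right-skewed (Pearson against severity is intentionally not offered). All
correlations use pairwise-complete observations and report the per-pair N.
p-values are Benjamini–Hochberg adjusted within one family per reported
table (each blood×CSF table and each severity grid per sub-cohort is its
own family — the most conservative reading of per-table presentation);
significance is adjusted p < 0.05. Spearman p-values use the
t-approximation with average ranks, switching to an exact permutation p
for N ≤ 9.

## The synthetic cohort generator

Per analyte j, subject i, visit t, on the latent (pre-skew) scale:

    y_ijt = fixed_ij + s_ij + e_ijt,
    s_ij  = sign_j·L_j·F_{i,c(j)} + √(1 − L_j²)·u_ij

with unit-variance latent factors F shared within a cluster, loadings
L ∈ [0,1] (default 0.8), sign −1 for negative APRs, and independent
standard-normal subject noise u, so the stable part has unit variance and
same-cluster analytes correlate at the product of their (signed) loadings.
`fixed` collects diagnosis shifts and standardized-covariate effects. The
visit-noise variance is solved analytically from

    σe² = (1 + Var[fixed]) · (1 − ICC*) / ICC*

where Var[fixed] is computed *exactly* by enumerating diagnosis×sex×race
cells with normal age moments — so the one-way ICC equals the target in
expectation even with confounding switched on; the target is never tuned.
Right skew is induced by the inverse Box-Cox transform with analyte-specific
exponents (heavier for CRP/ferritin) after rescaling to unit variance and
offsetting by +4, giving marginals with a realistic ~25% coefficient of
variation; the pipeline's Box-Cox step then has something real to undo.
Severity is an affine map of the latent CSF predictor onto the 0–10
MSSS-like scale (0–6 for the MS-DSS-like scale) with small per-visit
noise; couplings are configured on the Spearman scale and converted to
Pearson slopes via 2·sin(πρ/6). Missingness is completely at random on
biomarker and severity cells only.

Defaults mirror the study design being emulated: 51 HD, 118 RRMS and 173
progressive-MS subjects (split 87 PPMS / 86 SPMS), uniform 1–8 visits,
age means 39/42/55 years (progressive patients older), per-group sex and
race frequencies, 10% biomarker and 20% severity missingness, ICC target
0.9, CSF-humoral→severity Spearman coupling 0.25, and zero blood↔CSF
coupling — so the default cohort reproduces the qualitative published
picture: elevated CSF clusters in MS, a severity association for the
humoral CSF cluster, and no cross-compartment correlation.

**What the generator does not emulate.** Assay units and calibration,
longitudinal progression dynamics, informative dropout, diagnosis-dependent
severity offsets, and non-Gaussian latent dependence. Passing recovery
tests therefore demonstrates that the pipeline's estimators are unbiased
and calibrated under the generative assumptions the analysis itself makes
— not that those assumptions hold in any particular clinical dataset.

## Numerical and validation choices

- **Problem sizes.** Validation suites use single-visit cohorts of ~300
  subjects for structure recovery (100 seeds), the study's 51/118/173
  group sizes for effect recovery (200 seeds) and null calibration (500
  cohorts), and 500×4 designs for ICC calibration — sizes at which each
  check's Monte-Carlo error is small relative to its tolerance.
- **Effect-recovery scenario** uses noiseless repeated measures
  (ICC target 1) so the generator's SD unit and the pipeline's Z unit
  coincide and the check isolates estimator bias; with visit noise the
  pooled-SD inflation alone contributes a known ≈ −0.02 shrinkage.
- **Box-Cox identifiability.** At λ* = 1 the marginal is normal with CV
  0.25, a near-affine regime where the exponent is weakly identified
  (per-sample SE ≈ 0.23 at n = 300 for any estimator); recovery is
  therefore asserted on the across-seed median, which is unbiased.
- **Null calibration.** Under the global null the per-family rate of any
  BH-adjusted p < 0.05 runs at ≈ 5%; small cohorts show mild tail
  inflation (~6.5%) from residual post-transform non-normality, shrinking
  at the study's size. The asserted bound is 7%.
- **Determinism.** All randomness flows from `numpy.random.default_rng`
  seeds; derivation orders are independent of dict insertion order; report
  files are written with fixed float formatting, so identical inputs give
  byte-identical outputs.
- **Degenerate inputs** raise typed errors: undefined ICC designs,
  zero-variance analytes, duplicate subject-visit keys, rank-deficient
  designs (naming analyte and term), groups with <2 values, pairs with
  <10 complete observations during derivation (advising the frozen
  partition), correlations with N < 3 (flagged, excluded from FDR).

## Known limitations

- The adjustment assumes linear covariate effects on the transformed
  scale; strongly non-linear age effects would leak into residuals.
- Connected-component clustering is transitive: one borderline edge can
  merge otherwise distinct clusters; the frozen layout avoids this by
  construction, and the threshold is configurable.
- MSSS/ARMSS/MS-DSS are consumed as given; their reference-matrix
  construction is out of scope.
- BH is applied per table; pooling families across tables would be more
  stringent and is not offered as a switch.
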