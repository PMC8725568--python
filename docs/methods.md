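# Methods

## The two-stage polytomous model

Let tumors be cross-classified by ER, PR, HER2 (negative/positive) and
histologic grade (1/2/3) into M = 24 cells, enumerated lexicographically
with negative/grade-1 as reference. For subject *i* with genotype dosage
g ∈ [0, 2] and covariates x (ancestry PCs), the first stage is a
multinomial logistic model against the control category,

    η_m = α_m + β_m g + ξᵀx,    P(cell m) = e^{η_m} / (1 + Σ_j e^{η_j}),

and the second stage constrains β = Aθ. Supported designs:

* `main_effects` (p = 5): baseline plus one case-case parameter per
  marker; binary markers coded 0/1 (negative reference), grade coded
  0/1/2 ordinally, so θ_grade is a per-grade-step case-case log-OR.
* `subtype_indicators` (p = 5): β constant within each intrinsic-like
  subtype (luminal A-like: HR+, HER2−, grade 1–2; luminal B-like/HER2−:
  HR+, HER2−, grade 3; luminal B-like/HER2+: HR+, HER2+, any grade;
  HER2+/non-luminal: ER−PR−HER2+; triple-negative: ER−PR−HER2−; HR+ means
  ER+ and/or PR+). The luminal B-like/HER2+ definition carries no grade
  restriction. Summing cells within a subtype shows this is exactly a
  5-category polytomous model, so θ are subtype-vs-control log-ORs.
* `grade_indicators` (p = 3): per-grade log-ORs.
* `saturated` (p = M): one free log-OR per cell.

Intercepts α are saturated (one per cell, capturing the case subtype mix
and the case-control sampling fractions); covariate coefficients ξ are
shared across cells. Both choices keep the parameter count at M + p + k
instead of M(1 + k) + p; subtype-specific covariate effects are out of
scope.

## Missing markers and estimation

A case with a partially observed pattern contributes
log Σ_{m ∈ S} P(cell m), where S is the set of cells consistent with its
observed values (MAR assumption). Controls contribute log P(control); a
case with all four markers missing still informs θ₀ through its genotype.

Two equivalent maximizers are provided:

* **Newton** (default): the gradient and Hessian of the observed-data
  log-likelihood are computed in closed form. In the cell-logit space the
  per-subject curvature is (diag w − wwᵀ) − (diag P − PPᵀ), with w the
  posterior over S; all parameter-space blocks reduce to matrix products,
  so one iteration is O(nM) + O((M+p+k)³). Steps are damped by
  backtracking line search and are ascent steps by construction.
* **EM**: E-step posteriors w over the consistent cells; M-step maximizes
  the complete-data Q-function by Newton (its Hessian is the standard
  multinomial one). The observed log-likelihood is monotone across
  iterations. Because EM converges linearly when missing information is
  substantial, a final monotone Newton refinement of the last iterate is
  applied when the score has not yet met tolerance; the recorded
  likelihood trace remains non-decreasing and both modes agree with the
  direct optimum to well below 1e-5 on θ.

Convergence: max |score| < 1e-6 (absolute) for Newton; the reported
`converged` flag uses the sample-size-scaled criterion
max |score| < max(gtol, 1e-7 n). Initialization: α from smoothed
case/control frequency ratios (pattern mass spread uniformly over
consistent cells), θ = 0, ξ = 0.

**Standard errors** are taken from the observed information of the
observed-data log-likelihood — correct under MAR — using the same
analytic Hessian as the optimizer (exact, not a finite-difference
approximation).

Degenerate situations are handled explicitly rather than silently:

* Cells never consistent with any case are removed from the category
  space (their MLE intercept is −∞); indicator-design columns supported
  only by removed cells are dropped and their categories reported as
  undefined.
* Intercepts drifting to −∞ for quasi-empty cells (possible under
  missingness) are clamped at −30, where the cell probability is ~1e-13.
* The observed-data likelihood is non-concave and can be flat along
  unidentified manifolds (e.g. grade missing for every case): the
  covariance is computed by eigen-floored inversion (eigenvalues below
  1e-8 × λ_max are floored), so weakly identified directions surface as
  visibly enormous SEs and a `weakly_identified` flag.
* A second-stage parameter exceeding |θ| > 12 with vanishing curvature
  raises a separation error (the MLE does not exist).

## Heterogeneity tests

* **Marker-specific (model 2)**: Wald z = θ_k / SE with two-sided normal
  p, from the joint main-effects fit (each marker adjusted for the
  others). No small-sample correction; intended cohort sizes are large.
* **Global, fixed (model 2 based)**: Wald quadratic form of the four
  case-case parameters, χ² with 4 df. θ₀ is excluded from the null — the
  hypothesis concerns heterogeneity, not overall association.
* **Global, mixed (model 1)**: θ_ER is fixed; θ_PR, θ_HER2, θ_grade are
  modeled as μ + b_k with b_k ~ N(0, σ²) sharing one mean and one
  variance (the minimal mixed structure with a well-defined boundary
  test). H₀: θ_ER = 0, μ = 0, σ² = 0. The statistic is computed from the
  efficient score U of the case-case parameters at the null fit (α, θ₀,
  ξ estimated; V = Schur-complement information): a 2-df Wald form in the
  fixed directions (e_ER and the random-mean contrast) plus an
  inverse-variance-standardized variance-component score Σ_k U_k²/V_kk
  over the random markers. As a quadratic form UᵀMU with U ~ N(0, V)
  under H₀, its null law is Σ λ_j χ²₁ with λ the eigenvalues of
  V^{1/2}MV^{1/2}. The exact combination used by the original analysis is
  not printed in its main text; this is a statistically valid boundary
  score test and the Monte Carlo evaluation is the reference
  implementation for verifying the analytic tail.
* **Tail probabilities**: Imhof's inversion integral evaluated on a dense
  grid with an oscillation-aware truncation bound (r = 1 reduces to an
  exact scaled χ²₁); agreement with exact χ² cases is ~1e-9 and with
  Monte Carlo (10⁵ draws) within 0.005. 
* **FDR**: Benjamini–Hochberg step-up q-values (via statsmodels) over all
  variants in a screen; default gate q < 0.05.
* **Meta-analysis**: per-stratum estimates combined by multivariate
  inverse-variance fixed-effect meta-analysis; for the mixed test,
  per-stratum scores and informations are summed before forming the
  statistic (exact under independent strata). Strata share no parameters;
  PCs are stratum-specific.

## The screen (pipeline)

For each variant: model-1 p per stratum combined across strata → BH-FDR
over all screened variants → for FDR-significant variants, model-2 marker
tests and model-3 subtype ORs (meta-combined) → model-4 grade ORs for
variants whose only marker-specific p < 0.05 is grade. Variants failing
convergence are reported with NA and a status note, not dropped silently.
Reporting clusters rows/columns of the |z| matrices by complete-linkage
hierarchical clustering on Euclidean distance (average/ward available);
heatmap colors show signed z. Plotted numbers are exported as TSV next to
every figure.

## Synthetic cohorts

The generator reproduces the structure the analysis assumes, calibrated
to the published descriptive distribution of the BCAC two-array case
population (stored in `calibration.py`):

* **Markers** follow a latent-Gaussian threshold model. Cutpoints come
  from the reference prevalences (ER+ 81%, PR+ 68%, HER2+ 17%, grade
  20/49/31). Latent correlations are solved numerically (bivariate-normal
  rectangle probabilities + Brent root finding) so the *observed-scale*
  Pearson correlations of the coded markers match their targets: the
  three reference values r(ER,PR) = 0.61, r(ER,HER2) = −0.16,
  r(ER,grade) = −0.39, and for the three unreported pairs the defaults
  (PR,HER2) = −0.05, (PR,grade) = −0.42, (HER2,grade) = 0.16 — chosen
  once so the implied intrinsic-like-subtype mix lands within ±2
  percentage points of the reference shares (54/13/13/6/14) while keeping
  the signs clinically sensible. The reference margins, the fixed ER–PR
  correlation, and subtype shares over *classifiable* cases are not
  exactly mutually consistent, so the remaining pairs cannot tune every
  share to zero error.
* **Genotypes**: controls are Hardy–Weinberg draws at the configured MAF;
  case genotypes are drawn exactly from the 3-point tilted law
  P(g | case, cell m) ∝ f(g)e^{β_m g} with β = Aθ_true, so the fitted
  model is correctly specified and fixed case/control totals affect only
  intercepts. Optional beta-distributed jitter emulates imputed dosages.
* **Missingness**: per-marker Bernoulli masking of case markers; default
  rates from the reference table (ER 0.19, PR 0.27, HER2 0.46,
  grade 0.27). Rates may depend on stratum and on *observed* ER status
  (ER's own missingness is independent); masking can never depend on the
  value being masked — requesting that raises, keeping the mechanism MAR
  by construction.
* **Scale**: default stratum sizes mirror the reference study
  (71,788/58,134 and 34,783/37,628); tests and examples override with
  desk-scale sizes. PCs are standard normal with null effects by default.

What the simulator does not emulate: linkage disequilibrium between
variants, study-level heterogeneity beyond the two array strata,
population stratification actually correlated with genotype, laboratory
batch structure in marker assays, or MNAR missingness. Passing tests
demonstrate correctness of the estimators and tests under a correctly
specified MAR data-generating process — not robustness to violations of
those assumptions on real data.

## Verification design and problem sizes

The test suite checks closed-form toys (2×2 tables with analytic
log-ORs), exact oracle equivalence of the saturated two-stage MLE with an
independently fitted multinomial logit (1e-6), EM/Newton agreement and EM
monotonicity, brute-force posteriors for the E-step, hand-computed BH and
meta-analysis arithmetic, and simulation-based properties: parameter
recovery and 95% CI coverage under MAR (100 replicates of n = 20,000),
null calibration of both global tests (500 replicates of n = 5,000,
judged against the exact central binomial region), power strictly above
the nominal level under pure ER heterogeneity, and the precision ordering
between the EM analysis and the complete-case sensitivity analysis.
Simulation sizes were chosen to keep the default suite within a
half-hour on one CPU while leaving Monte Carlo margins; saturated-design
oracle tests use a flat, independent marker model so that every cell is
well populated (the realistic mix leaves some of the 24 cells nearly
empty at desk scale, where per-cell MLEs sit near boundaries).

Two known estimator facts surface in the tests' tolerances: separate
category-vs-control logistic fits are a *conditional* likelihood and
differ from the joint polytomous MLE by Op(1/n) (agreement asserted at
5e-3 for n = 40,000, not exact equality), and score-based and Wald-based
global tests can disagree noticeably on individual draws at non-null
parameters even though both are calibrated under the null.

## Limitations

* Second-stage interactions between markers are not modeled.
* The mixed-effects structure (common μ, common σ²) is one defensible
  choice; marker-specific variances would need a multi-component boundary
  test.
* Case-control sampling is handled prospectively (intercepts absorb the
  design); efficiency refinements from the retrospective likelihood are
  not implemented.
* Inference is asymptotic throughout; no exact small-sample or
  permutation procedures.
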