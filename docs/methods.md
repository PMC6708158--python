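# Methods

This note documents the statistical models implemented in `epiclock`,
the generative model behind the synthetic worlds, the numerical choices
that matter, and what the passing test suite does and does not show
about real methylation data.

## 1. Variance components (`epiclock.varcomp`)

**Model.** With `y` the vector of chronological ages and `Z` the
column-standardized (mean 0, sample SD 1, `n−1` denominator) beta
matrix over `m` probes, the omics relationship matrix is `K = ZZ′/m`.
The single-component mixed model is

    y = W b + g + e,   g ~ N(0, K σu²),   e ~ N(0, I σe²),

with `W` the fixed effects (always an intercept; extra covariates
optional) and the target quantity `ρ² = σu²/(σu² + σe²)`, the fraction
of age variance captured jointly by all probes.

**Estimation.** Restricted maximum likelihood, solved exactly rather
than by iterative score updates: the fixed effects are removed by an
orthonormal rotation `A` (`A′W = 0`, `A′A = I`), `A′KA` is
eigendecomposed once, and the restricted likelihood — profiled over the
total variance `σp² = σu² + σe²` — is maximized over `ρ² ∈ [0, 1]` with
bounded Brent search (`xatol = 1e-12`), evaluating the two boundary
values explicitly.  This is robust at the boundaries, which real data
reaches (whole-methylome fits of age land at `ρ̂² = 1`).  Standard
errors come from the Fisher information in `(σu², σe²)` at the
(possibly constrained) optimum, mapped to `ρ²` by the delta method;
boundary fits are flagged, and the information there is reported at the
constrained optimum.  The permutation test shuffles ages across
individuals and refits; the empirical p is `(1 + #{ρ̂²_perm ≥
ρ̂²_obs})/(n_perm + 1)`.

**Identifiability caveat.** When `K`'s spectrum is close to a flat
bulk (near-independent probes, `n < m`), `σu²K + σe²I` is weakly
identified and both the null and the noiseless limits are soft: null
draws of `ρ̂²` can reach ~0.15 at `n = 400`, and a noiseless phenotype
is pulled to ~0.98 rather than 1.0.  Structured worlds (batch and
cell-composition factors, which disperse the spectrum the way real
probe correlation does) and tall probe blocks (`n > m`) sharpen both,
and the tests exercise the boundaries under those conditions.

## 2. Clock training (`epiclock.clocks`)

Both estimators operate on the training-standardized matrix, and every
clock stores its per-probe training mean and SD plus the beta-value
transform tag, making it portable: applying a clock to a new matrix
imputes missing probes at the training mean (zero contribution after
centering, with a missing-fraction report and an error above 50%).

* **BLUP.**  Probe effects `û = Z′(ZZ′ + (m σe²/σu²) I)⁻¹ (y − ȳ)` —
  the mixed-model solution, identical to ridge regression with penalty
  `m σe²/σu²`.  The `n × n` dual system is solved by dense Cholesky-
  style factorization and back-substituted to probe effects (`n ≪ m`
  in all regimes of interest).  The variance ratio comes from a REML
  fit on the training data unless supplied; `σu² = 0` collapses the
  clock to the training mean age with a warning.
* **Elastic Net.**  Coordinate-descent minimization of
  `(1/2n)‖y − a − Zβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` via scikit-learn's
  `ElasticNet`/`ElasticNetCV`; the solution is verified in the tests
  against the Karush–Kuhn–Tucker conditions and, at `α = 0`, against
  the closed-form ridge solution.  Defaults: `α = 0.5` (configurable),
  10-fold cross-validation with shuffled, seeded folds, minimum-MSE
  penalty rule, convergence tolerance `1e-4` on the coefficient-update
  criterion (tightened locally wherever an oracle comparison needs it).
  The CV seed and fold count are recorded in the clock metadata.
* **Transforms.**  Power `BV^λ` over the conventional grid λ = 0.1 to
  2.0 in steps of 0.05 (39 values), M-value `log2(b/(1−b))`,
  arcsine-sqrt, and natural log; the unbounded transforms clip at
  `ε = 1e-3` because simulated betas can approach the bounds.
* **Pruning.**  Greedy windowed correlation pruning: probes are
  scanned in column order and dropped when `r²` with any retained
  probe within the trailing window (default 500) exceeds the threshold
  (default 0.2).  The exact pruning recipe used on real arrays is not
  standardized; this deterministic variant is the package's choice.
* **Training designs.**  For C cohorts, every size k = 1…C−1 gets
  `n_replicates` uniform without-replacement draws of k training
  cohorts; the unselected cohorts are the test sets.  14 cohorts with
  5 replicates give the canonical 65 training sets.

## 3. Evaluation (`epiclock.evaluation`)

RMSE and Pearson correlation per (clock, test cohort); correlation on a
constant vector is flagged undefined (NaN) rather than coerced to 0.
The conventional display rule of excluding points with RMSE > 15 years
from figures is carried as a flag (`plot_excluded`) and never enters
any statistic.  `factor_regression` fits OLS of accuracy on training
size, the absolute train/test mean-age difference and the training-age
SD, with a collinearity flag.

## 4. Survival association (`epiclock.survival`)

The age acceleration residual (AAR) is the residual from regressing
predicted on chronological age (intercept included, so residuals sum
to zero within the fitted group).  A perfect clock has AAR ≡ 0, and the
Cox wrapper then raises a zero-variance-covariate error — the logical
point that a perfect chronological-age clock carries no information
about biological age is enforced rather than papered over.

The Cox engine maximizes the partial likelihood by Newton–Raphson with
step-halving, Efron tie handling (Breslow by flag), convergence when
the largest coefficient update is below `1e-9`, and a divergence guard
(|β| > 50) that reports monotone likelihood/separation.  Covariates:
age, sex, and the technical factors (plate, array, position,
hybridization date) as one-hot fixed effects; the WBC sensitivity
analysis adds the five measured cell counts.  Hazard ratios for AAR are
reported per 5 years of acceleration, `exp(5β)`, with a 95% Wald CI
from the same `β` and SE as the reported z statistic.  The engine is
validated against an independent partial-likelihood implementation and
against the log-rank statistic (score test at β = 0, binary covariate,
no ties).

The attenuation experiment holds one cohort out of *all* clock
training, computes AAR there for each training set in a design, and
records the Cox z with and without WBC adjustment.

## 5. EWAS and enrichment (`epiclock.ewas`)

Per probe, simple linear regression of beta on AAR (no further
covariates by default; the real analyses leave this choice open),
two-sided p from the t distribution with `n−2` df, Bonferroni threshold
`0.05 / m_tested` with `m_tested` the probes actually tested in the
run, and `λ_median = median(t²)/qchisq(0.5, 1)` as the inflation
summary.  Zero-variance probes are skipped and counted.

Enrichment of the significant probes in the heterogeneity set uses
Fisher's exact test (two-sided, by summation of hypergeometric
probabilities no larger than the observed table's — verified exactly
against full enumeration in the tests).  The odds ratio is the
conditional MLE with an exact CI, the convention of mainstream exact-
test routines; the raw cross-product ratio and its Haldane–Anscombe
(+0.5) corrected version are also emitted because small or empty cells
are routine in this analysis (a clock with few EWAS hits produces
degenerate tables, reported as "no evidence of enrichment": OR NaN,
CI (0, ∞), p = 1).  For trends across training sizes, pooling the 2×2
tables over replicates before forming the corrected OR is the stable
summary used by the tests and the acceptance script.

## 6. The synthetic-data generator (`epiclock.synthetic`)

The generator emulates a multi-cohort blood-methylation study of
chronological age.  Defaults describe the reference world: six cohorts
(60/240/70/160/70/300 samples) whose age ranges echo the typical mix —
two narrow elderly birth cohorts, a young family study, three broad
adult cohorts — 2000 probes of which 200 are causal for age, a target
variance fraction of 0.9, five blood cell types, a heterogeneity probe
fraction of 0.23, and a composition effect on mortality.

**Probes.**  Logit-scale construction throughout: bimodal baselines
(most CpGs near fully methylated/unmethylated), cohort-level batch
shifts (`N(0, 0.05²)` per cohort × probe — chosen so that cohort
transfer biases are a few years, as observed in real cross-cohort
prediction, not tens of years), iid measurement noise
(`N(0, 0.3²)`), cell-type effects on the heterogeneity subset
(`N(0, 0.8²)` per probe × cell type, applied through the sample's cell
proportions), and the age signal on the causal subset.  The inverse-
logit keeps betas in (0, 1) with no hard clipping.

**Age signal and ρ² targeting.**  The causal block follows the
*conditional law of the forward mixed model*:

    x_causal | age  ~  N(a c z_age,  σ² I − a² c c′),

with equal-magnitude random-sign effect directions `c` and `z_age` the
standardized age.  The negative rank-one noise correction cancels the
marginal inter-probe correlation that the shared age factor would
otherwise induce, so the causal probes are marginally exchangeable —
exactly what the REML model assumes — and the causal index is the
optimal linear predictor of age.  Without the correction, REML at
`n = 400 < m = 1000` overshoots the single-index R² by ~0.2 at
ρ² = 0.5; with it, recovery is unbiased.  The scalar `a` is calibrated
by root finding on the realized beta-scale R² of age on the causal
index, so the recorded `realized_rho2` equals the configured target to
root-finding precision.

**Cell composition and confounding.**  Logistic-normal proportions
around realistic blood fractions (neutrophils ≈ 56%, lymphocytes ≈
33%, …).  The age-composition coupling acts on within-cohort
standardized age with a **per-cohort random coefficient**
(`confounding_strength × N(0,1)`): the observable age-composition
association differs between real cohorts (recruitment, disease makeup,
processing), and this inconsistency is what lets a single-cohort clock
exploit its local composition-age correlation while pooled training
averages the channel away.  A globally consistent coupling would make
composition a *stable* age predictor that larger training sets learn
*better*, inverting the attenuation phenomenon; the per-cohort design
is therefore a modeling commitment, not a convenience.

**Mortality.**  Exponential (or Weibull, proportional-hazards form)
times with log-hazard `0.085·(age − mean age) + b·z(cell)` where
`z(cell)` is the standardized proportion of a designated cell type
(default: neutrophils; effect 0.7 per SD), administrative censoring at
15 years plus 10% uniform early dropout.  Measured WBC counts are
lognormal-noised transforms of the true proportions (CV 10%) times a
lognormal total count, because the sensitivity analysis should see
measured counts, not truth.

**Determinism.**  One seed; independent sub-streams (phenotypes,
probes, WBC measurement, mortality) via `SeedSequence` spawn keys, so
identical configs give byte-identical output files.

**What the generator does not emulate.**  Genomic autocorrelation of
probes along the chromosome, array-intensity artifacts, non-blood
tissues, family/genetic relatedness between samples, disease effects on
methylation, and any nonlinearity of the age-methylation relation
beyond the logit link.  Passing tests therefore demonstrate internal
correctness and the qualitative mechanisms (size–accuracy trade-off,
composition confounding and its decay), not quantitative agreement
with any particular real cohort.

## 7. Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run scaled-down worlds
chosen as the package's reference conditions: variance-component
recovery at n = 400 samples × 1000 probes (20 seeds × four signal
levels); the training-size curve on six 120-sample cohorts with a
sparse (10-probe) signal; the confounding experiments on five
120-sample training cohorts plus a 250-sample narrow-age holdout with
150 causal probes and 1000 total.  The whole suite completes in a few
minutes on one CPU; all randomness is seed-derived.

## 8. Known limitations

* The single-component REML assumes exchangeable probe effects; under
  strong probe correlation the estimand drifts from the causal-index
  R² (this is a property of the method, shared with its real-data
  uses, and the reason the generator decorrelates the causal block).
* The Cox engine targets small/medium problems (dense suffix-sum
  aggregation, O(n p²) memory for the risk-set cross-products); it is
  not tuned for biobank-scale survival data.
* The Elastic Net inherits scikit-learn's coordinate-descent
  convergence behavior; pathological penalty/correlation combinations
  can stop at the iteration cap with a warning.
* `prune_probes` is O(m × window) with a Python inner loop — adequate
  for the simulated scales, not for 450K-array-wide pruning.
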